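"""Per-locus and concatenated sequence diversity statistics.

Replicates the classic MLST descriptive table: fragment length, allele
count, polymorphic sites, synonymous/nonsynonymous SNP sites, nucleotide
diversity per site (pi), G+C content, and the Nei-Gojobori (1986) dN/dS
ratio with Jukes-Cantor correction.

Conventions
-----------
* Statistics are computed over all isolate sequences, not deduplicated
  alleles, so pi is the mean pairwise difference between two randomly
  selected isolates (an ST-deduplicated mode is available).
* pi uses the plain mean over unordered pairs, no n/(n-1) correction.
* Sites containing 'N' are excluded pairwise, never listwise.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

from Bio.Data.CodonTable import standard_dna_table

from .seqdata_io import LengthError, MLSTError, STOP_CODONS

logger = logging.getLogger(__name__)

_CODE = dict(standard_dna_table.forward_table)  # codon -> amino acid, stops absent
_BASES = "ACGT"


class FrameError(MLSTError):
    pass


class UndefinedStatisticError(MLSTError):
    pass


@dataclass
class DiversityRow:
    """One row of the descriptive diversity table."""

    locus: str
    length_bp: int
    n_alleles: int
    n_polymorphic_sites: int
    n_ssnp: int
    n_nsnp: int
    pi: float
    gc_percent: float
    dnds: float | None  # None = undefined (dS == 0 with dN > 0)
    dnds_degenerate: bool = False


def _check_alignment(alignment: list[str], min_seqs: int = 2) -> int:
    if len(alignment) < min_seqs:
        raise MLSTError(f"need >= {min_seqs} sequences, got {len(alignment)}")
    lengths = {len(s) for s in alignment}
    if len(lengths) != 1:
        raise LengthError(f"unequal sequence lengths: {sorted(lengths)}")
    return lengths.pop()


def count_polymorphic_sites(alignment: list[str]) -> tuple[int, list[int]]:
    """Count sites with >= 2 distinct non-N characters.

    Variation visible only through 'N' does not make a site polymorphic.
    Returns the count and the 0-based site list.
    """
    length = _check_alignment(alignment)
    sites = []
    for j in range(length):
        chars = {s[j] for s in alignment} - {"N"}
        if len(chars) >= 2:
            sites.append(j)
    return len(sites), sites


def nucleotide_diversity(alignment: list[str]) -> float:
    """Mean pairwise nucleotide difference per site (pi).

    Each unordered pair contributes (differences at mutually non-N sites) /
    (number of mutually non-N sites); pairs with zero comparable sites are
    excluded with a warning.  No small-sample correction is applied.
    """
    _check_alignment(alignment)
    total = 0.0
    used = 0
    skipped = 0
    for a, b in itertools.combinations(alignment, 2):
        comparable = 0
        diffs = 0
        for x, y in zip(a, b):
            if x == "N" or y == "N":
                continue
            comparable += 1
            if x != y:
                diffs += 1
        if comparable == 0:
            skipped += 1
            continue
        total += diffs / comparable
        used += 1
    if skipped:
        logger.warning("%d pair(s) with zero comparable sites excluded", skipped)
    if used == 0:
        raise UndefinedStatisticError("no sequence pair with comparable sites")
    return total / used


def gc_content(alignment: list[str]) -> float:
    """Pooled G+C percentage over all non-N bases of all sequences."""
    if not alignment:
        raise MLSTError("empty alignment")
    gc = 0
    total = 0
    for s in alignment:
        for c in s:
            if c == "N":
                continue
            total += 1
            if c in "GC":
                gc += 1
    if total == 0:
        raise UndefinedStatisticError("all-N input: G+C content undefined")
    return 100.0 * gc / total


def _codon_columns(alignment: list[str], frame_offset: int) -> list[list[str]]:
    """Observed full codons per codon position (N-containing codons dropped)."""
    length = len(alignment[0])
    n_codons = (length - frame_offset) // 3
    cols: list[list[str]] = []
    for k in range(n_codons):
        start = frame_offset + 3 * k
        cols.append(
            [s[start : start + 3] for s in alignment if "N" not in s[start : start + 3]]
        )
    return cols


def _majority_frame_check(cols: list[list[str]]) -> None:
    for k, codons in enumerate(cols[:-1]):  # terminal codon may be a stop
        if not codons:
            continue
        counts: dict[str, int] = {}
        for c in codons:
            counts[c] = counts.get(c, 0) + 1
        majority = max(counts, key=lambda c: (counts[c], c))
        if majority in STOP_CODONS:
            raise FrameError(f"internal stop codon {majority} at codon {k}")


def classify_snp_sites(
    alignment: list[str], frame_offset: int = 0
) -> tuple[int, int, dict[int, set[str]]]:
    """Label polymorphic sites as synonymous and/or nonsynonymous.

    For each polymorphic site, all observed full codons covering it are
    enumerated; the site is synonymous if some pair of observed codons
    differing only at that site encodes the same amino acid, and
    nonsynonymous if some such pair encodes different amino acids (a change
    to or from a stop counts as nonsynonymous).  A site may carry both
    labels.  Sites falling in incomplete terminal codons are skipped with a
    warning.
    """
    length = _check_alignment(alignment)
    if length - frame_offset < 3:
        raise FrameError("alignment shorter than one codon after frame_offset")
    _, sites = count_polymorphic_sites(alignment)
    cols = _codon_columns(alignment, frame_offset)
    _majority_frame_check(cols)
    n_codons = len(cols)
    labels: dict[int, set[str]] = {}
    for j in sites:
        k = (j - frame_offset) // 3
        if j < frame_offset or k >= n_codons:
            logger.warning("site %d outside complete codons: skipped", j)
            continue
        within = (j - frame_offset) % 3
        observed = sorted(set(cols[k]))
        site_labels: set[str] = set()
        for c1, c2 in itertools.combinations(observed, 2):
            diff_pos = [i for i in range(3) if c1[i] != c2[i]]
            if diff_pos != [within]:
                continue
            aa1, aa2 = _CODE.get(c1), _CODE.get(c2)  # None = stop
            if aa1 is not None and aa1 == aa2:
                site_labels.add("s")
            else:
                site_labels.add("n")
        if site_labels:
            labels[j] = site_labels
    n_ssnp = sum("s" in v for v in labels.values())
    n_nsnp = sum("n" in v for v in labels.values())
    return n_ssnp, n_nsnp, labels


def _codon_site_counts(codon: str) -> tuple[float, float]:
    """Potential synonymous/nonsynonymous sites of one codon (NG86).

    Each position contributes the fraction of its three possible changes
    that are synonymous; changes to stop codons count as nonsynonymous.
    """
    aa = _CODE.get(codon)
    if aa is None:
        raise FrameError(f"stop codon {codon} in coding sequence")
    s = 0.0
    for i in range(3):
        syn = 0
        for b in _BASES:
            if b == codon[i]:
                continue
            alt = codon[:i] + b + codon[i + 1 :]
            if _CODE.get(alt) == aa:
                syn += 1
        s += syn / 3.0
    return s, 3.0 - s


def _pathway_changes(c1: str, c2: str) -> tuple[float, float]:
    """Observed synonymous/nonsynonymous differences between two codons.

    Codons differing at 2-3 positions are averaged with equal weight over
    all minimal mutational pathways; pathways passing through a stop codon
    are discarded (if every pathway hits a stop, all are kept).
    """
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0
    pathways = []
    for order in itertools.permutations(diff):
        cur = c1
        sd = nd = 0.0
        blocked = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS and len(diff) > 1:
                blocked = True
            aa1, aa2 = _CODE.get(cur), _CODE.get(nxt)
            if aa1 is not None and aa1 == aa2:
                sd += 1
            else:
                nd += 1
            cur = nxt
        pathways.append((blocked, sd, nd))
    open_paths = [(sd, nd) for blocked, sd, nd in pathways if not blocked]
    if not open_paths:
        open_paths = [(sd, nd) for _, sd, nd in pathways]
    sd = sum(p[0] for p in open_paths) / len(open_paths)
    nd = sum(p[1] for p in open_paths) / len(open_paths)
    return sd, nd


def _jukes_cantor(p: float) -> float:
    if p >= 0.75:
        raise UndefinedStatisticError(f"proportion {p:.4f} >= 3/4: correction undefined")
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def nei_gojobori(
    alignment: list[str],
    frame_offset: int = 0,
    correction: str = "jukes_cantor",
) -> tuple[float, float, float | None]:
    """Nei-Gojobori (1986) dN, dS and their ratio.

    Potential sites come from codon mutational opportunity, observed
    differences from equal-weight pathway averaging, per-pair proportions
    are corrected with the Jukes-Cantor formula (``correction="none"``
    skips it), and dN/dS is the ratio of the over-pair means.  Pairs whose
    proportion reaches 3/4 are dropped with a warning.  Returns
    ``dnds=None`` when dS == 0 with dN > 0 (undefined), and 0.0 when
    dN == 0.
    """
    if correction not in ("jukes_cantor", "none"):
        raise ValueError(f"unknown correction {correction!r}")
    _check_alignment(alignment)
    n_pairs = 0
    dn_sum = 0.0
    ds_sum = 0.0
    dropped = 0
    site_cache: dict[str, tuple[float, float]] = {}

    def seq_sites(codons: list[str]) -> tuple[float, float]:
        s = n = 0.0
        for c in codons:
            if c not in site_cache:
                site_cache[c] = _codon_site_counts(c)
            cs, cn = site_cache[c]
            s += cs
            n += cn
        return s, n

    for a, b in itertools.combinations(alignment, 2):
        codons_a, codons_b = [], []
        length = len(a)
        for start in range(frame_offset, length - 2, 3):
            ca, cb = a[start : start + 3], b[start : start + 3]
            if "N" in ca or "N" in cb:
                continue
            codons_a.append(ca)
            codons_b.append(cb)
        if not codons_a:
            continue
        s_a, n_a = seq_sites(codons_a)
        s_b, n_b = seq_sites(codons_b)
        s_bar, n_bar = (s_a + s_b) / 2.0, (n_a + n_b) / 2.0
        sd = nd = 0.0
        for ca, cb in zip(codons_a, codons_b):
            psd, pnd = _pathway_changes(ca, cb)
            sd += psd
            nd += pnd
        if s_bar == 0 or n_bar == 0:
            continue
        ps, pn = sd / s_bar, nd / n_bar
        try:
            if correction == "jukes_cantor":
                ds, dn = _jukes_cantor(ps), _jukes_cantor(pn)
            else:
                ds, dn = ps, pn
        except UndefinedStatisticError:
            dropped += 1
            continue
        ds_sum += ds
        dn_sum += dn
        n_pairs += 1
    if dropped:
        logger.warning("%d saturated pair(s) dropped from dN/dS", dropped)
    if n_pairs == 0:
        return 0.0, 0.0, 0.0
    dn, ds = dn_sum / n_pairs, ds_sum / n_pairs
    if dn == 0.0:
        return dn, ds, 0.0
    if ds == 0.0:
        return dn, ds, None
    return dn, ds, dn / ds


def diversity_report(
    dataset,
    table,
    unit: str = "isolates",
    dnds_correction: str = "jukes_cantor",
) -> list[DiversityRow]:
    """One DiversityRow per locus plus a concatenated row.

    ``unit="isolates"`` (default) computes statistics over every isolate
    sequence; ``unit="sts"`` deduplicates to one representative per ST.
    """
    from .seqdata_io import concatenate

    if unit not in ("isolates", "sts"):
        raise ValueError(f"unknown unit {unit!r}")
    rows: list[DiversityRow] = []
    concat = concatenate(dataset, "per_st" if unit == "sts" else "per_isolate",
                         table if unit == "sts" else None)
    total_s = total_n = 0
    for locus, (start, end) in zip(dataset.loci, concat.boundaries):
        seqs = [row[start:end] for row in concat.matrix]
        n_poly, _ = count_polymorphic_sites(seqs)
        pi = nucleotide_diversity(seqs)
        gc = gc_content(seqs)
        if locus.coding:
            n_ssnp, n_nsnp, _ = classify_snp_sites(seqs, locus.frame_offset)
            dn, ds, dnds = nei_gojobori(seqs, locus.frame_offset, dnds_correction)
            degenerate = dn == 0.0 and ds == 0.0
        else:
            n_ssnp = n_nsnp = 0
            dnds, degenerate = 0.0, True
        total_s += n_ssnp
        total_n += n_nsnp
        rows.append(
            DiversityRow(
                locus=locus.name,
                length_bp=locus.fragment_length,
                n_alleles=len(table.catalogs[locus.name]),
                n_polymorphic_sites=n_poly,
                n_ssnp=n_ssnp,
                n_nsnp=n_nsnp,
                pi=pi,
                gc_percent=gc,
                dnds=dnds,
                dnds_degenerate=degenerate,
            )
        )
    whole = concat.matrix
    n_poly_all, _ = count_polymorphic_sites(whole)
    n_distinct = len(set(whole))
    rows.append(
        DiversityRow(
            locus="concatenated",
            length_bp=concat.total_length,
            n_alleles=n_distinct,
            n_polymorphic_sites=n_poly_all,
            n_ssnp=total_s,
            n_nsnp=total_n,
            pi=nucleotide_diversity(whole),
            gc_percent=gc_content(whole),
            dnds=None,
            dnds_degenerate=False,
        )
    )
    return rows


def write_report_tsv(path, rows: list[DiversityRow]) -> None:
    """Tab-separated diversity table in the canonical column order."""
    with open(path, "w") as fh:
        fh.write(
            "locus\tlength\talleles\tpolymorphic_sites\tsSNP\tnSNP\tpi\tgc_percent\tdnds\n"
        )
        for r in rows:
            dnds = "undefined" if r.dnds is None else f"{r.dnds:.4f}"
            fh.write(
                f"{r.locus}\t{r.length_bp}\t{r.n_alleles}\t{r.n_polymorphic_sites}"
                f"\t{r.n_ssnp}\t{r.n_nsnp}\t{r.pi:.5f}\t{r.gc_percent:.2f}\t{dnds}\n"
            )
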