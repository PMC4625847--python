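"""Reading, validation and assembly of per-locus MLST sequence fragments.

An MLST scheme types isolates by short (here 415-641 bp) internal fragments
of housekeeping genes, one FASTA file per locus with record IDs naming the
isolates.  This module turns those files plus an isolate metadata table into
a complete, rectangular :class:`MLSTDataset` (every isolate has exactly one
equal-length sequence at every locus) and produces concatenated alignments
for phylogenetic analysis.

Coordinates are 0-based half-open throughout.  Fragments are treated as
gap-free pre-aligned sequences; 'N' is accepted on input and handled
pairwise by downstream statistics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

from Bio import SeqIO

logger = logging.getLogger(__name__)

ALPHABET = frozenset("ACGTN")

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})


class MLSTError(Exception):
    """Base class for errors raised by this package."""


class FastaParseError(MLSTError):
    pass


class DuplicateRecordError(MLSTError):
    pass


class AlphabetError(MLSTError):
    pass


class LengthError(MLSTError):
    pass


class DegenerateLocusError(MLSTError):
    pass


class EmptyDatasetError(MLSTError):
    pass


@dataclass(frozen=True)
class LocusDef:
    """Definition of one housekeeping-gene fragment.

    Parameters
    ----------
    name : str
        Short locus label, e.g. ``"clpX"``.
    fragment_length : int
        Expected trimmed fragment length in bp.
    frame_offset : int
        Index (0, 1 or 2) of the first complete codon position within the
        fragment; relevant only for coding loci.
    coding : bool
        Whether the fragment is protein-coding (enables codon-based
        statistics such as dN/dS).
    """

    name: str
    fragment_length: int
    frame_offset: int = 0
    coding: bool = True

    def __post_init__(self) -> None:
        if self.fragment_length <= 0:
            raise ValueError(f"{self.name}: fragment_length must be > 0")
        if self.frame_offset not in (0, 1, 2):
            raise ValueError(f"{self.name}: frame_offset must be 0, 1 or 2")
        if self.coding and self.fragment_length - self.frame_offset < 3:
            raise ValueError(
                f"{self.name}: coding fragment must contain at least one full codon"
            )


@dataclass(frozen=True)
class SequenceRecord:
    """One sequence fragment of one isolate at one locus."""

    isolate_id: str
    locus: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise AlphabetError(f"{self.isolate_id}/{self.locus}: empty sequence")
        bad = set(self.sequence) - ALPHABET
        if bad:
            pos = next(
                i for i, c in enumerate(self.sequence) if c not in ALPHABET
            )
            raise AlphabetError(
                f"illegal character {self.sequence[pos]!r} at position {pos} "
                f"in isolate {self.isolate_id!r} (locus {self.locus})"
            )


@dataclass(frozen=True)
class IsolateMeta:
    """Metadata for one isolate: ecological source and geographic region."""

    isolate_id: str
    source: str = "unknown"
    region: str = "unknown"
    is_reference: bool = False


@dataclass
class MLSTDataset:
    """Complete rectangular matrix of trimmed fragments.

    Invariants (enforced on construction): every isolate has exactly one
    sequence per locus, and all sequences of one locus share that locus's
    ``fragment_length``.
    """

    loci: list[LocusDef]
    sequences: dict[tuple[str, str], str]
    metadata: dict[str, IsolateMeta] = field(default_factory=dict)

    def __post_init__(self) -> None:
        locus_names = [l.name for l in self.loci]
        if len(set(locus_names)) != len(locus_names):
            raise ValueError("duplicate locus names")
        isolates = {iso for iso, _ in self.sequences}
        for iso in isolates:
            for loc in self.loci:
                key = (iso, loc.name)
                if key not in self.sequences:
                    raise EmptyDatasetError(
                        f"isolate {iso!r} missing locus {loc.name!r}"
                    )
                if len(self.sequences[key]) != loc.fragment_length:
                    raise LengthError(
                        f"isolate {iso!r} locus {loc.name!r}: length "
                        f"{len(self.sequences[key])} != {loc.fragment_length}"
                    )
        self._isolates = sorted(isolates)
        for iso in self._isolates:
            self.metadata.setdefault(iso, IsolateMeta(iso))

    @property
    def isolates(self) -> list[str]:
        """Isolate IDs in lexicographic order."""
        return list(self._isolates)

    @property
    def locus_names(self) -> list[str]:
        return [l.name for l in self.loci]

    @property
    def n_isolates(self) -> int:
        return len(self._isolates)

    def locus(self, name: str) -> LocusDef:
        for l in self.loci:
            if l.name == name:
                return l
        raise KeyError(name)

    def alignment(self, locus: str) -> list[tuple[str, str]]:
        """(isolate_id, sequence) pairs for one locus, in isolate order."""
        return [(iso, self.sequences[(iso, locus)]) for iso in self._isolates]

    def summary(self) -> str:
        """Tab-separated dataset summary (one row per locus + totals)."""
        lines = ["locus\tlength_bp\tcoding\tframe_offset\tn_isolates"]
        for l in self.loci:
            lines.append(
                f"{l.name}\t{l.fragment_length}\t{int(l.coding)}"
                f"\t{l.frame_offset}\t{self.n_isolates}"
            )
        total = sum(l.fragment_length for l in self.loci)
        lines.append(f"total\t{total}\t-\t-\t{self.n_isolates}")
        return "\n".join(lines) + "\n"


@dataclass
class ConcatenatedAlignment:
    """Equal-length concatenation of the per-locus fragments.

    ``boundaries`` holds 0-based half-open per-locus offsets partitioning
    ``[0, total_length)`` in locus order.
    """

    ids: list[str]
    matrix: list[str]
    boundaries: list[tuple[int, int]]
    locus_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.matrix):
            raise ValueError("ids and matrix length mismatch")
        total = self.boundaries[-1][1] if self.boundaries else 0
        for row in self.matrix:
            if len(row) != total:
                raise LengthError("row length does not match boundaries")
        pos = 0
        for start, end in self.boundaries:
            if start != pos or end <= start:
                raise ValueError("boundaries must partition [0, total) in order")
            pos = end

    @property
    def total_length(self) -> int:
        return self.boundaries[-1][1] if self.boundaries else 0

    def write_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for name, row in zip(self.ids, self.matrix):
                fh.write(f">{name}\n{row}\n")


def read_locus_fasta(path, locus: str) -> list[SequenceRecord]:
    """Read one locus FASTA; record IDs become isolate IDs.

    Sequences are uppercased; the isolate ID is the first
    whitespace-delimited token of the header.  Raises on duplicate IDs or
    characters outside ``{A,C,G,T,N}``.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    try:
        parsed = list(SeqIO.parse(str(path), "fasta"))
    except ValueError as exc:  # Biopython signals malformed FASTA this way
        raise FastaParseError(f"{path}: {exc}") from exc
    for rec in parsed:
        iso = rec.id
        if iso in seen:
            raise DuplicateRecordError(
                f"{path}: duplicate isolate_id {iso!r} in locus {locus!r}"
            )
        seen.add(iso)
        records.append(SequenceRecord(iso, locus, str(rec.seq).upper()))
    if not records:
        logger.warning("%s: empty FASTA for locus %s", path, locus)
    return records


def write_locus_fasta(path, records: list[SequenceRecord]) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.isolate_id}\n{rec.sequence}\n")


def validate_and_trim(
    records: list[SequenceRecord],
    locus: LocusDef,
    mode: str = "strict",
) -> tuple[list[SequenceRecord], LocusDef]:
    """Enforce equal fragment lengths.

    ``strict``: every sequence must already equal ``locus.fragment_length``.
    ``trim_to_shortest``: truncate all sequences at the right end to the
    shortest length present and update ``fragment_length`` accordingly.
    """
    if mode not in ("strict", "trim_to_shortest"):
        raise ValueError(f"unknown mode {mode!r}")
    if not records:
        return [], locus
    if mode == "strict":
        bad = [r.isolate_id for r in records if len(r.sequence) != locus.fragment_length]
        if bad:
            raise LengthError(
                f"locus {locus.name!r}: isolates with length != "
                f"{locus.fragment_length}: {', '.join(sorted(bad))}"
            )
        return list(records), locus
    shortest = min(len(r.sequence) for r in records)
    if shortest - locus.frame_offset < 9:
        raise DegenerateLocusError(
            f"locus {locus.name!r}: trimmed length {shortest} below 3 codons"
        )
    trimmed = [replace(r, sequence=r.sequence[:shortest]) for r in records]
    new_locus = replace(locus, fragment_length=shortest)
    return trimmed, new_locus


def detect_frame_offset(sequences: list[str]) -> int:
    """Choose the reading frame (0/1/2) with zero internal stop codons.

    Evaluated across all distinct sequences; among stop-free frames the
    smallest offset wins; if no frame is stop-free the offset with the
    fewest stops is returned (smallest on ties).
    """
    distinct = sorted(set(sequences))
    best = (float("inf"), 0)
    for off in (0, 1, 2):
        stops = 0
        for seq in distinct:
            usable = len(seq) - off
            n_codons = usable // 3
            for k in range(n_codons - 1):  # exclude the terminal codon
                if seq[off + 3 * k : off + 3 * k + 3] in STOP_CODONS:
                    stops += 1
        if stops == 0:
            return off
        if (stops, off) < best:
            best = (stops, off)
    return best[1]


def build_dataset(
    per_locus: dict[str, list[SequenceRecord]],
    meta: list[IsolateMeta] | None = None,
    loci: list[LocusDef] | None = None,
) -> tuple[MLSTDataset, list[str]]:
    """Assemble per-locus records into a complete dataset.

    Isolates missing any locus are dropped (returned in the rejected list,
    with a warning); metadata rows without sequences are ignored.  If
    ``loci`` is omitted, each locus's ``fragment_length`` is taken from the
    records (which must already be equal-length) and ``frame_offset`` is
    auto-detected.
    """
    if not per_locus:
        raise EmptyDatasetError("no loci supplied")
    locus_names = list(per_locus)
    isolate_sets = [
        {r.isolate_id for r in recs} for recs in per_locus.values()
    ]
    complete = sorted(set.intersection(*isolate_sets)) if isolate_sets else []
    all_isolates = sorted(set.union(*isolate_sets))
    rejected = sorted(set(all_isolates) - set(complete))
    if rejected:
        logger.warning(
            "dropping %d isolate(s) with incomplete locus coverage: %s",
            len(rejected), ", ".join(rejected),
        )
    if not complete:
        raise EmptyDatasetError("zero isolates with complete data at all loci")

    if loci is None:
        loci = []
        for name in locus_names:
            recs = per_locus[name]
            lengths = {len(r.sequence) for r in recs}
            if len(lengths) != 1:
                raise LengthError(
                    f"locus {name!r}: unequal lengths {sorted(lengths)}; "
                    "run validate_and_trim first"
                )
            length = lengths.pop()
            off = detect_frame_offset([r.sequence for r in recs])
            loci.append(LocusDef(name, length, frame_offset=off, coding=True))

    sequences: dict[tuple[str, str], str] = {}
    for name, recs in per_locus.items():
        for r in recs:
            if r.isolate_id in set(complete):
                sequences[(r.isolate_id, name)] = r.sequence

    metadata: dict[str, IsolateMeta] = {}
    complete_set = set(complete)
    for m in meta or []:
        if m.isolate_id in complete_set:
            metadata[m.isolate_id] = m
        else:
            logger.warning("metadata row for unknown isolate %r ignored", m.isolate_id)
    return MLSTDataset(loci, sequences, metadata), rejected


def concatenate(
    dataset: MLSTDataset,
    taxa: str = "per_isolate",
    profiles=None,
) -> ConcatenatedAlignment:
    """Concatenate loci in the dataset's declared order.

    ``per_isolate`` emits one row per isolate; ``per_st`` (requires a
    :class:`~mlstpop.allele_typing.ProfileTable`) emits one row per sequence
    type, built from that ST's allele sequences, labelled ``ST<n>``.
    """
    boundaries: list[tuple[int, int]] = []
    pos = 0
    for l in dataset.loci:
        boundaries.append((pos, pos + l.fragment_length))
        pos += l.fragment_length
    if taxa == "per_isolate":
        ids = dataset.isolates
        matrix = [
            "".join(dataset.sequences[(iso, l.name)] for l in dataset.loci)
            for iso in ids
        ]
    elif taxa == "per_st":
        if profiles is None:
            raise TypeError("per_st concatenation requires a ProfileTable")
        ids = [f"ST{st}" for st in sorted(profiles.st_profiles)]
        matrix = []
        for st in sorted(profiles.st_profiles):
            prof = profiles.st_profiles[st]
            parts = []
            for locus_name, allele_num in zip(profiles.locus_order, prof):
                parts.append(profiles.catalogs[locus_name].alleles[allele_num - 1])
            matrix.append("".join(parts))
    else:
        raise ValueError(f"unknown taxa mode {taxa!r}")
    return ConcatenatedAlignment(ids, matrix, boundaries, dataset.locus_names)


def read_metadata_tsv(path) -> list[IsolateMeta]:
    """Read the isolate metadata table.

    Tab-separated with header ``isolate_id<TAB>source<TAB>region<TAB>is_reference``.
    """
    rows: list[IsolateMeta] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        expected = ["isolate_id", "source", "region", "is_reference"]
        if header != expected:
            raise MLSTError(f"{path}: expected header {expected}, got {header}")
        for line in fh:
            if not line.strip():
                continue
            iso, source, region, ref = line.rstrip("\n").split("\t")
            rows.append(IsolateMeta(iso, source, region, ref in ("1", "true", "True")))
    return rows


def write_metadata_tsv(path, meta: list[IsolateMeta]) -> None:
    with open(path, "w") as fh:
        fh.write("isolate_id\tsource\tregion\tis_reference\n")
        for m in meta:
            fh.write(f"{m.isolate_id}\t{m.source}\t{m.region}\t{int(m.is_reference)}\n")
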