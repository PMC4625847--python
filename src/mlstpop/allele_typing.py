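"""Allele cataloguing and sequence-type (ST) assignment.

Every distinct nucleotide sequence at a locus defines an allele, numbered
1..K in first-observation order; the vector of allele numbers across loci
(the allelic profile) defines the sequence type.  Isolates are processed in
lexicographic ID order so numbering is deterministic for a given dataset;
comparisons with externally published ST labels are meaningful only up to
relabeling.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

from .seqdata_io import LengthError, MLSTDataset, MLSTError, SequenceRecord


@dataclass
class AlleleCatalog:
    """Distinct sequences of one locus, numbered densely from 1."""

    locus: str
    alleles: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(set(self.alleles)) != len(self.alleles):
            raise MLSTError(f"{self.locus}: catalog sequences not distinct")
        if len({len(a) for a in self.alleles}) > 1:
            raise LengthError(f"{self.locus}: catalog sequences of unequal length")
        self.lookup: dict[str, int] = {a: i + 1 for i, a in enumerate(self.alleles)}

    def __len__(self) -> int:
        return len(self.alleles)

    def number_of(self, sequence: str) -> int:
        return self.lookup[sequence]


AllelicProfile = tuple[int, ...]


@dataclass
class ProfileTable:
    """Allele catalogs plus the ST <-> profile <-> isolate mapping."""

    locus_order: list[str]
    catalogs: dict[str, AlleleCatalog]
    st_profiles: dict[int, AllelicProfile]
    st_members: dict[int, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        profs = list(self.st_profiles.values())
        if len(set(profs)) != len(profs):
            raise MLSTError("ST profiles not pairwise distinct")
        seen: set[str] = set()
        for members in self.st_members.values():
            for iso in members:
                if iso in seen:
                    raise MLSTError(f"isolate {iso!r} assigned to multiple STs")
                seen.add(iso)

    @property
    def n_sts(self) -> int:
        return len(self.st_profiles)

    @property
    def n_loci(self) -> int:
        return len(self.locus_order)

    def st_size(self, st: int) -> int:
        return len(self.st_members.get(st, []))

    def st_of_isolate(self) -> dict[str, int]:
        return {iso: st for st, members in self.st_members.items() for iso in members}


def catalog_alleles(records: list[SequenceRecord] | list[str], locus: str = "") -> AlleleCatalog:
    """Build an allele catalog from equal-length sequences.

    Numbering follows first observation in input order; every input
    sequence maps to exactly one allele number.  Sequences containing 'N'
    are catalogued as distinct literal strings (no merging of ambiguous
    variants).
    """
    if not records:
        raise MLSTError("cannot catalog an empty alignment")
    seqs: list[str] = []
    for r in records:
        seq = r.sequence if isinstance(r, SequenceRecord) else r
        if not locus and isinstance(r, SequenceRecord):
            locus = r.locus
        seqs.append(seq)
    if len({len(s) for s in seqs}) > 1:
        raise LengthError(f"{locus}: unequal sequence lengths in catalog input")
    alleles: list[str] = []
    seen: set[str] = set()
    for s in seqs:
        if s not in seen:
            seen.add(s)
            alleles.append(s)
    return AlleleCatalog(locus, alleles)


def assign_profiles(dataset: MLSTDataset) -> ProfileTable:
    """Catalog alleles at every locus and assign STs.

    Isolates are scanned in lexicographic ID order; allele numbers and ST
    numbers are assigned by first observation in that scan, so the result
    is a pure function of the dataset content.
    """
    locus_order = dataset.locus_names
    catalogs: dict[str, AlleleCatalog] = {}
    for name in locus_order:
        catalogs[name] = catalog_alleles(
            [seq for _, seq in dataset.alignment(name)], name
        )
    st_profiles: dict[int, AllelicProfile] = {}
    st_members: dict[int, list[str]] = {}
    profile_to_st: dict[AllelicProfile, int] = {}
    for iso in dataset.isolates:
        profile = tuple(
            catalogs[name].number_of(dataset.sequences[(iso, name)])
            for name in locus_order
        )
        st = profile_to_st.get(profile)
        if st is None:
            st = len(profile_to_st) + 1
            profile_to_st[profile] = st
            st_profiles[st] = profile
            st_members[st] = []
        st_members[st].append(iso)
    return ProfileTable(locus_order, catalogs, st_profiles, st_members)


def export_profiles(table: ProfileTable, outdir) -> None:
    """Write the PubMLST-style profile TSV and per-locus allele FASTAs.

    Profile file: ``ST<TAB>locus1..locusL<TAB>count``; allele FASTAs use IDs
    ``locus_alleleNumber``.  :func:`import_profiles` round-trips exactly.
    """
    os.makedirs(outdir, exist_ok=True)
    ppath = os.path.join(outdir, "profiles.tsv")
    try:
        with open(ppath, "w") as fh:
            fh.write("ST\t" + "\t".join(table.locus_order) + "\tcount\n")
            for st in sorted(table.st_profiles):
                prof = table.st_profiles[st]
                fh.write(
                    f"{st}\t" + "\t".join(map(str, prof)) + f"\t{table.st_size(st)}\n"
                )
        for name in table.locus_order:
            cat = table.catalogs[name]
            with open(os.path.join(outdir, f"{name}_alleles.fasta"), "w") as fh:
                for i, seq in enumerate(cat.alleles, start=1):
                    fh.write(f">{name}_{i}\n{seq}\n")
    except OSError as exc:
        raise MLSTError(f"failed writing profiles under {outdir}: {exc}") from exc


def import_profiles(outdir) -> ProfileTable:
    """Re-read files written by :func:`export_profiles`."""
    ppath = os.path.join(outdir, "profiles.tsv")
    with open(ppath) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[0] != "ST" or header[-1] != "count":
            raise MLSTError(f"{ppath}: not a profile table")
        locus_order = header[1:-1]
        st_profiles: dict[int, AllelicProfile] = {}
        counts: dict[int, int] = {}
        for line in fh:
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            st = int(parts[0])
            st_profiles[st] = tuple(int(x) for x in parts[1:-1])
            counts[st] = int(parts[-1])
    catalogs: dict[str, AlleleCatalog] = {}
    from Bio import SeqIO

    for name in locus_order:
        fpath = os.path.join(outdir, f"{name}_alleles.fasta")
        alleles = [str(r.seq).upper() for r in SeqIO.parse(fpath, "fasta")]
        catalogs[name] = AlleleCatalog(name, alleles)
    # member lists are not serialized in the profile dialect; keep counts as
    # anonymous placeholder members so st_size round-trips
    st_members = {
        st: [f"ST{st}_member{i + 1}" for i in range(counts[st])] for st in st_profiles
    }
    return ProfileTable(locus_order, catalogs, st_profiles, st_members)
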