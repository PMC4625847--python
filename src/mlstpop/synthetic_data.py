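"""Synthetic clonal MLST populations with known ground truth.

Emulates the structure of a housekeeping-gene MLST study of a bacterial
species: 8 protein-coding loci of 415-641 bp, clonal descent with rare
point mutation (transition/transversion weighted), occasional whole-locus
exchange between co-existing isolates (recombination at allele
granularity), and planted clonal-complex structure via diverged founder
genotypes.

The model is a sequential clonal birth process: the first ``n_founders``
isolates are exact copies of the founder genotypes; every later isolate
copies a uniformly chosen earlier isolate of the same founder lineage and
accumulates ``generations`` rounds of per-site mutation.  After the
population is complete, ``generations`` rounds of whole-locus recombination
are applied population-wide.  Every event is logged, and replaying the
logs from the founder sequences reproduces the emitted dataset exactly.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np

from .seqdata_io import (
    STOP_CODONS,
    IsolateMeta,
    LocusDef,
    MLSTDataset,
    write_locus_fasta,
    write_metadata_tsv,
    SequenceRecord,
)

_BASES = "ACGT"
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {
    "A": "CT", "G": "CT", "C": "AG", "T": "AG",
}
_SOURCES = ["pickle", "sourdough", "dairy", "fermented_vegetable", "silage"]

DEFAULT_LOCI = [
    LocusDef("clpX", 443), LocusDef("groEL", 519), LocusDef("murC", 462),
    LocusDef("murE", 573), LocusDef("pheS", 441), LocusDef("pyrG", 456),
    LocusDef("recA", 516), LocusDef("uvrC", 620),
]


@dataclass
class SimConfig:
    """Parameters of the clonal population simulator.

    Defaults emulate a study-scale collection: 186 isolates typed at 8
    coding loci, 10 planted founder lineages, rare mutation and occasional
    whole-locus recombination.
    """

    n_isolates: int = 186
    loci: list[LocusDef] = field(default_factory=lambda: list(DEFAULT_LOCI))
    n_founders: int = 10
    mutation_rate: float = 1e-5       # per site per generation
    titv_ratio: float = 2.0
    recombination_rate: float = 0.01  # per isolate per generation
    generations: int = 10
    founder_divergence: float = 0.02  # per-site divergence between founders
    seed: int = 0

    def __post_init__(self) -> None:
        for name, rate in (
            ("mutation_rate", self.mutation_rate),
            ("recombination_rate", self.recombination_rate),
            ("founder_divergence", self.founder_divergence),
        ):
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.titv_ratio <= 0:
            raise ValueError("titv_ratio must be > 0")
        if not self.loci:
            raise ValueError("need at least one locus")
        if not 1 <= self.n_founders <= self.n_isolates:
            raise ValueError("need 1 <= n_founders <= n_isolates")
        if self.generations < 0:
            raise ValueError("generations must be >= 0")


@dataclass
class SimTruth:
    """Ground truth of one simulated population."""

    founder_assignment: dict[str, int]
    genealogy: dict[str, str | None]          # isolate -> parent (None = founder copy)
    founder_seqs: dict[int, dict[str, str]]   # founder index -> locus -> sequence
    birth_order: list[str]
    mutation_log: list[tuple[str, str, int, str, str]]  # iso, locus, pos, from, to
    recombination_log: list[tuple[int, str, str, str]]  # round, recipient, donor, locus
    seed: int = 0

    def to_json(self, path) -> None:
        payload = {
            "seed": self.seed,
            "founder_assignment": self.founder_assignment,
            "genealogy": self.genealogy,
            "founder_seqs": {str(k): v for k, v in self.founder_seqs.items()},
            "birth_order": self.birth_order,
            "mutation_log": [list(e) for e in self.mutation_log],
            "recombination_log": [list(e) for e in self.recombination_log],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def _random_coding_sequence(length: int, rng: np.random.Generator) -> str:
    """Random sequence with no internal stop codon in frame 0."""
    seq = list(rng.choice(list(_BASES), size=length))
    n_codons = length // 3
    for k in range(n_codons):  # internal gene fragment: no in-frame stop at all
        while "".join(seq[3 * k : 3 * k + 3]) in STOP_CODONS:
            seq[3 * k : 3 * k + 3] = list(rng.choice(list(_BASES), size=3))
    return "".join(seq)


def _creates_stop(seq: list[str], pos: int, base: str, frame_offset: int) -> bool:
    k = (pos - frame_offset) // 3
    if pos < frame_offset or k < 0:
        return False
    start = frame_offset + 3 * k
    if start + 3 > len(seq):
        return False
    codon = seq[start:start + 3]
    codon[pos - start] = base
    return "".join(codon) in STOP_CODONS


def mutate_sequence(
    seq: str,
    rate: float,
    titv_ratio: float,
    rng: np.random.Generator,
    coding_guard: bool = False,
    frame_offset: int = 0,
) -> tuple[str, list[tuple[int, str, str]]]:
    """Mutate each site independently with the given probability.

    Substitutions are transitions with probability titv/(titv+1), with the
    remaining mass split equally over the two transversions.  With the
    coding guard on, substitutions that would create an internal in-frame
    stop codon are rejected (the site keeps its base).  Returns the new
    sequence and the (position, from, to) event list in position order.
    """
    if rate == 0.0:
        return seq, []
    hits = np.nonzero(rng.random(len(seq)) < rate)[0]
    if hits.size == 0:
        return seq, []
    chars = list(seq)
    p_ts = titv_ratio / (titv_ratio + 1.0)
    events: list[tuple[int, str, str]] = []
    for pos in hits:
        pos = int(pos)
        old = chars[pos]
        if old == "N":
            continue
        u = rng.random()
        if u < p_ts:
            new = _TRANSITION[old]
        else:
            tv = _TRANSVERSIONS[old]
            new = tv[0] if (u - p_ts) < (1.0 - p_ts) / 2.0 else tv[1]
        if coding_guard and _creates_stop(chars, pos, new, frame_offset):
            continue
        chars[pos] = new
        events.append((pos, old, new))
    return "".join(chars), events


def apply_recombination(
    population: dict[str, dict[str, str]],
    rate: float,
    rng: np.random.Generator,
    locus_names: list[str] | None = None,
    round_index: int = 0,
) -> list[tuple[int, str, str, str]]:
    """One round of whole-locus exchange.

    Per isolate (in sorted ID order), with the given probability one
    uniformly chosen locus is replaced by that locus from a uniformly
    chosen other isolate's *current* state.  Events are returned as
    (round, recipient, donor, locus) in application order.
    """
    isolates = sorted(population)
    if len(isolates) < 2:
        raise ValueError("recombination needs >= 2 isolates")
    if locus_names is None:
        locus_names = sorted(population[isolates[0]])
    events: list[tuple[int, str, str, str]] = []
    for iso in isolates:
        if rng.random() >= rate:
            continue
        locus = locus_names[int(rng.integers(len(locus_names)))]
        donor = iso
        while donor == iso:
            donor = isolates[int(rng.integers(len(isolates)))]
        population[iso][locus] = population[donor][locus]
        events.append((round_index, iso, donor, locus))
    return events


def simulate_population(cfg: SimConfig) -> tuple[MLSTDataset, SimTruth]:
    """Simulate one clonal population; deterministic for a given seed."""
    rng = np.random.default_rng(cfg.seed)
    locus_names = [l.name for l in cfg.loci]

    founders: dict[int, dict[str, str]] = {}
    base: dict[str, str] = {
        l.name: _random_coding_sequence(l.fragment_length, rng) for l in cfg.loci
    }
    founders[0] = dict(base)
    for f in range(1, cfg.n_founders):
        genotype: dict[str, str] = {}
        for l in cfg.loci:
            while True:
                seq, _ = mutate_sequence(
                    base[l.name], cfg.founder_divergence, cfg.titv_ratio, rng,
                    coding_guard=l.coding, frame_offset=l.frame_offset,
                )
                if all(seq != founders[g][l.name] for g in range(f)):
                    break
            genotype[l.name] = seq
        founders[f] = genotype

    width = max(3, len(str(cfg.n_isolates)))
    ids = [f"iso{i:0{width}d}" for i in range(cfg.n_isolates)]
    assignment = {ids[i]: i % cfg.n_founders for i in range(cfg.n_isolates)}
    population: dict[str, dict[str, str]] = {}
    genealogy: dict[str, str | None] = {}
    mutation_log: list[tuple[str, str, int, str, str]] = []
    by_founder: dict[int, list[str]] = {f: [] for f in range(cfg.n_founders)}

    for i, iso in enumerate(ids):
        f = assignment[iso]
        if i < cfg.n_founders:
            population[iso] = dict(founders[f])
            genealogy[iso] = None
        else:
            parent = by_founder[f][int(rng.integers(len(by_founder[f])))]
            genealogy[iso] = parent
            genotype = dict(population[parent])
            for l in cfg.loci:
                seq = genotype[l.name]
                for _ in range(cfg.generations):
                    seq, events = mutate_sequence(
                        seq, cfg.mutation_rate, cfg.titv_ratio, rng,
                        coding_guard=l.coding, frame_offset=l.frame_offset,
                    )
                    for pos, old, new in events:
                        mutation_log.append((iso, l.name, pos, old, new))
                genotype[l.name] = seq
            population[iso] = genotype
        by_founder[f].append(iso)

    recombination_log: list[tuple[int, str, str, str]] = []
    if cfg.recombination_rate > 0 and cfg.n_isolates >= 2:
        for r in range(cfg.generations):
            recombination_log.extend(
                apply_recombination(
                    population, cfg.recombination_rate, rng, locus_names, r
                )
            )

    sequences = {
        (iso, name): population[iso][name] for iso in ids for name in locus_names
    }
    metadata = {
        iso: IsolateMeta(
            iso,
            source=_SOURCES[assignment[iso] % len(_SOURCES)],
            region=f"region{assignment[iso] % 4 + 1}",
        )
        for iso in ids
    }
    dataset = MLSTDataset(list(cfg.loci), sequences, metadata)
    truth = SimTruth(
        founder_assignment=assignment,
        genealogy=genealogy,
        founder_seqs=founders,
        birth_order=ids,
        mutation_log=mutation_log,
        recombination_log=recombination_log,
        seed=cfg.seed,
    )
    return dataset, truth


def replay_truth(truth: SimTruth, loci: list[LocusDef]) -> dict[str, dict[str, str]]:
    """Rebuild the final sequences from founders plus the event logs."""
    locus_names = [l.name for l in loci]
    muts: dict[str, list[tuple[str, int, str, str]]] = {}
    for iso, locus, pos, old, new in truth.mutation_log:
        muts.setdefault(iso, []).append((locus, pos, old, new))
    population: dict[str, dict[str, str]] = {}
    for iso in truth.birth_order:
        parent = truth.genealogy[iso]
        if parent is None:
            genotype = dict(truth.founder_seqs[truth.founder_assignment[iso]])
        else:
            genotype = dict(population[parent])
        for locus, pos, old, new in muts.get(iso, []):
            seq = genotype[locus]
            assert seq[pos] == old, "mutation log inconsistent with state"
            genotype[locus] = seq[:pos] + new + seq[pos + 1 :]
        population[iso] = genotype
    for _, recipient, donor, locus in truth.recombination_log:
        population[recipient][locus] = population[donor][locus]
    return population


def write_simulated(outdir, dataset: MLSTDataset, truth: SimTruth) -> None:
    """Emit the FASTA-per-locus + metadata TSV layout plus truth JSON."""
    os.makedirs(outdir, exist_ok=True)
    for locus in dataset.locus_names:
        records = [
            SequenceRecord(iso, locus, seq) for iso, seq in dataset.alignment(locus)
        ]
        write_locus_fasta(os.path.join(outdir, f"{locus}.fasta"), records)
    write_metadata_tsv(
        os.path.join(outdir, "metadata.tsv"),
        [dataset.metadata[iso] for iso in dataset.isolates],
    )
    truth.to_json(os.path.join(outdir, "truth.json"))
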