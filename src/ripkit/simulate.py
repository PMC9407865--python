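"""Synthetic-data generator for every input the pipeline consumes.

The generator fabricates, from a single integer seed:

* a random bait locus with a gene model (exon/intron structure inside
  5'/3' flanks) and a repeat-consensus library,
* per-breed assembly-derived locus sequences in which carrier breeds
  harbour a consensus copy inserted with a duplicated target site (TSD),
  optional reverse-complement orientation, per-copy point divergence,
  and locus-wide background SNPs / small (<50 bp) indels,
* per-breed genotype counts drawn from an inbreeding-adjusted
  Hardy-Weinberg trinomial,
* per-animal Gaussian trait values per genotype group,
* qPCR Ct tables whose group-wise true fold changes are realized in
  expectation, and dual-luciferase well tables with construct-specific
  mean firefly/renilla ratios.

All generators are pure functions of (config, seed): a single global
seed feeds named substreams so each stage can be regenerated
independently.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .model import (
    GENOTYPES,
    GeneModel,
    GenotypeCounts,
    LocusSequence,
    RepeatConsensus,
    revcomp,
)

__all__ = [
    "ConsensusSpec",
    "InsertionSpec",
    "BreedSpec",
    "PopulationSpec",
    "TraitSpec",
    "ExpressionSpec",
    "LuciferaseSpec",
    "SimConfig",
    "make_locus",
    "resolve_insertion_sites",
    "make_assemblies",
    "make_population",
    "make_phenotypes",
    "make_ct_table",
    "make_luciferase",
    "left_normalize_insertion",
    "default_locus_configs",
    "default_population_specs",
    "default_trait_specs",
    "default_expression_spec",
    "default_luciferase_spec",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")

# named substreams of the global seed
_STAGE_LOCUS, _STAGE_ASSEMBLY, _STAGE_POP, _STAGE_PHENO, _STAGE_CT, _STAGE_LUC = range(6)


def _rng(seed: int, stage: int, sub: int = 0) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(stage, sub)))


def _crc(label: str) -> int:
    return zlib.crc32(label.encode())


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode()


def _mutate_substitutions(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Apply point substitutions at the given per-base rate."""
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hits = np.nonzero(rng.random(arr.size) < rate)[0]
    for i in hits:
        alternatives = _BASES[_BASES != arr[i]]
        arr[i] = rng.choice(alternatives)
    return arr.tobytes().decode()


# --------------------------------------------------------------------------
# configuration records


@dataclass(frozen=True)
class ConsensusSpec:
    name: str
    length: int
    repeat_class: str = "SINE"


@dataclass(frozen=True)
class InsertionSpec:
    """One planted insertion: which consensus goes where, and how.

    ``site`` is either an absolute 0-based between-base breakpoint or a
    symbolic ``"intronK"`` placing the copy at the midpoint of intron K
    (transcription order) once the gene model is known.
    """

    consensus: str
    site: int | str
    strand: str = "+"
    tsd_len: int = 12
    divergence: float = 0.02

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError("insertion strand must be '+' or '-'")
        if not 0.0 <= self.divergence <= 0.2:
            raise ValueError("divergence must lie in [0, 0.2]")
        if self.tsd_len < 0:
            raise ValueError("negative TSD length")


@dataclass(frozen=True)
class BreedSpec:
    name: str
    carries: tuple[str, ...] = ()  # consensus names of carried insertions
    snp_rate: float = 0.01
    indel_rate: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.snp_rate < 1.0 or not 0.0 <= self.indel_rate < 1.0:
            raise ValueError("mutation rates must lie in [0, 1)")


@dataclass(frozen=True)
class PopulationSpec:
    breed: str
    n: int
    p_ins: float
    f: float = 0.0  # inbreeding coefficient

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("population size must be >= 1")
        if not 0.0 <= self.p_ins <= 1.0:
            raise ValueError("allele frequency outside [0,1]")
        if not -1.0 <= self.f <= 1.0:
            raise ValueError("inbreeding coefficient outside [-1,1]")


@dataclass(frozen=True)
class TraitSpec:
    """Gaussian trait: one (mean, sd) pair per genotype group."""

    name: str
    means: tuple[float, float, float]  # +/+, +/-, -/-
    sds: tuple[float, float, float]

    def __post_init__(self) -> None:
        if any(s < 0 for s in self.sds):
            raise ValueError("trait SDs must be non-negative")


@dataclass(frozen=True)
class ExpressionSpec:
    """qPCR design: per-group true fold change relative to the calibrator."""

    groups: tuple[tuple[str, float, int], ...]  # (label, fold, n samples)
    calibrator: str = "+/+"
    noise_sd: float = 0.2
    base_ct_reference: float = 17.0
    base_dct: float = 5.0
    reference_sd: float = 0.3

    def __post_init__(self) -> None:
        labels = [g[0] for g in self.groups]
        if self.calibrator not in labels:
            raise ValueError("calibrator group missing from expression spec")
        if any(g[1] <= 0 for g in self.groups):
            raise ValueError("fold changes must be positive")
        if self.noise_sd < 0:
            raise ValueError("negative Ct noise SD")


@dataclass(frozen=True)
class LuciferaseSpec:
    constructs: tuple[tuple[str, float, float, int], ...]  # (name, ratio, cv, n)
    control: str = "pGL3-basic"

    def __post_init__(self) -> None:
        names = [c[0] for c in self.constructs]
        if self.control not in names:
            raise ValueError("control construct missing from luciferase spec")
        if any(c[1] <= 0 or c[2] < 0 for c in self.constructs):
            raise ValueError("ratios must be positive and CVs non-negative")


@dataclass(frozen=True)
class SimConfig:
    """Full specification of one simulated locus and its cohort data."""

    seed: int
    gene_name: str = "GENE"
    locus_len: int = 15000
    n_exons: int = 3
    gene_strand: str = "+"
    flank5: int = 5000
    flank3: int = 3000
    exon_len: int = 150
    chrom: str = ""
    offset: int = 0
    library: tuple[ConsensusSpec, ...] = (
        ConsensusSpec("SINEA1_286", 286),
        ConsensusSpec("SINEA1_301", 301),
        ConsensusSpec("SINEA1_321", 321),
        ConsensusSpec("L1_frag", 1000, "LINE"),
    )
    insertions: tuple[InsertionSpec, ...] = ()
    breeds: tuple[BreedSpec, ...] = ()

    def __post_init__(self) -> None:
        names = [c.name for c in self.library]
        if len(set(names)) != len(names):
            raise ValueError("consensus names must be unique")
        for ins in self.insertions:
            if ins.consensus not in names:
                raise ValueError(f"insertion references unknown consensus {ins.consensus!r}")
        gene_space = self.locus_len - self.flank5 - self.flank3
        if gene_space < self.n_exons * self.exon_len + (self.n_exons - 1):
            raise ValueError("locus too short for the requested exon structure")


# --------------------------------------------------------------------------
# locus / assembly generation


def make_locus(cfg: SimConfig) -> tuple[LocusSequence, GeneModel, list[RepeatConsensus]]:
    """Generate the bait locus, its gene model, and the consensus library.

    Deterministic given ``cfg`` (byte-identical outputs for equal seeds).
    """
    rng = _rng(cfg.seed, _STAGE_LOCUS)
    seq = _random_dna(rng, cfg.locus_len)

    gene_start = cfg.flank5 + 1  # 1-based
    gene_end = cfg.locus_len - cfg.flank3
    region = gene_end - gene_start + 1
    n_introns = cfg.n_exons - 1
    intron_total = region - cfg.n_exons * cfg.exon_len
    intron_len = intron_total // n_introns if n_introns else 0
    exons = []
    pos = gene_start
    for i in range(cfg.n_exons):
        exons.append((pos, pos + cfg.exon_len - 1))
        pos += cfg.exon_len + intron_len
    model = GeneModel(cfg.gene_name, cfg.gene_strand, tuple(exons))

    library = [
        RepeatConsensus(c.name, c.repeat_class, _random_dna(rng, c.length))
        for c in cfg.library
    ]
    bait = LocusSequence(
        name=f"{cfg.gene_name}_bait",
        seq=seq,
        breed="reference",
        chrom=cfg.chrom,
        offset=cfg.offset,
    )
    # validate insertion sites now so misconfigurations fail early
    resolve_insertion_sites(cfg, model)
    return bait, model, library


def resolve_insertion_sites(cfg: SimConfig, model: GeneModel) -> dict[str, int]:
    """Map each insertion spec to its 0-based between-base breakpoint."""
    sites: dict[str, int] = {}
    for ins in cfg.insertions:
        if isinstance(ins.site, str):
            if not ins.site.lower().startswith("intron"):
                raise ValueError(f"unrecognized symbolic site {ins.site!r}")
            k = int(ins.site[6:])
            if model.n_introns == 0:
                raise ValueError(
                    f"gene {model.gene_name!r} has no introns; cannot place {ins.site!r}"
                )
            start, end = model.intron_interval(k)
            bp = (start - 1 + end) // 2
        else:
            bp = int(ins.site)
        if not ins.tsd_len <= bp <= cfg.locus_len:
            raise ValueError(
                f"breakpoint {bp} outside usable locus for {ins.consensus!r}"
            )
        sites[ins.consensus] = bp
    return sites


def left_normalize_insertion(bait_seq: str, pos: int, ins_seq: str) -> tuple[int, str]:
    """Shift an insertion to its leftmost equivalent placement.

    Insertions adjacent to sequence identical to their own tail are
    positionally ambiguous (the classic TSD/homopolymer ambiguity); the
    leftmost placement is the deterministic canonical form.
    """
    seq = ins_seq
    while pos > 0 and bait_seq[pos - 1] == seq[-1]:
        seq = bait_seq[pos - 1] + seq[:-1]
        pos -= 1
    return pos, seq


def make_assemblies(
    bait: LocusSequence,
    model: GeneModel,
    library: Sequence[RepeatConsensus],
    cfg: SimConfig,
) -> tuple[list[LocusSequence], pd.DataFrame]:
    """Generate one assembly-derived locus sequence per breed spec.

    Carrier breeds receive each carried consensus at its breakpoint with
    a duplicated TSD and per-copy point divergence; every breed then
    receives background SNPs and small (<50 bp) indels at its configured
    rates. Returns the sequences plus a ground-truth table with both the
    planted and the left-normalized breakpoints.

    Background indels are kept >= 50 bp away from planted insertions so
    the ground truth stays unambiguous.
    """
    lib = {c.name: c for c in library}
    sites = resolve_insertion_sites(cfg, model)
    truth_rows = []
    out = []
    for bi, breed in enumerate(cfg.breeds):
        rng = _rng(cfg.seed, _STAGE_ASSEMBLY, bi)
        seq = bait.seq
        carried = [ins for ins in cfg.insertions if ins.consensus in breed.carries]
        carried.sort(key=lambda ins: sites[ins.consensus], reverse=True)
        protected: list[tuple[int, int]] = []
        for ins in carried:
            bp = sites[ins.consensus]
            elem = lib[ins.consensus].seq
            if ins.strand == "-":
                elem = revcomp(elem)
            elem = _mutate_substitutions(elem, ins.divergence, rng)
            tsd = bait.seq[bp - ins.tsd_len : bp] if ins.tsd_len else ""
            inserted = elem + tsd
            seq = seq[:bp] + inserted + seq[bp:]
            bp_norm, _ = left_normalize_insertion(bait.seq, bp, inserted)
            truth_rows.append(
                {
                    "breed": breed.name,
                    "insertion": ins.consensus,
                    "strand": ins.strand,
                    "bait_pos": bp,
                    "bait_pos_norm": bp_norm,
                    "sv_len": len(inserted),
                    "element_len": len(elem),
                    "tsd": tsd,
                }
            )
        # final coordinates of planted segments, ascending
        shift = 0
        for ins in sorted(carried, key=lambda i: sites[i.consensus]):
            bp = sites[ins.consensus]
            span = len(lib[ins.consensus].seq) + ins.tsd_len
            protected.append((bp + shift - 50, bp + shift + span + 50))
            shift += span

        seq = _mutate_substitutions(seq, breed.snp_rate, rng)
        seq = _apply_small_indels(seq, breed.indel_rate, protected, rng)
        out.append(
            LocusSequence(
                name=f"{cfg.gene_name}_{breed.name}",
                seq=seq,
                breed=breed.name,
                chrom=cfg.chrom,
            )
        )
    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "breed", "insertion", "strand", "bait_pos", "bait_pos_norm",
            "sv_len", "element_len", "tsd",
        ],
    )
    return out, truth


def _apply_small_indels(
    seq: str,
    rate: float,
    protected: Sequence[tuple[int, int]],
    rng: np.random.Generator,
) -> str:
    if rate <= 0:
        return seq
    positions = np.nonzero(rng.random(len(seq)) < rate)[0]
    lengths = rng.integers(1, 50, size=positions.size)  # capped below the SV threshold
    is_ins = rng.random(positions.size) < 0.5
    s = seq
    for pos, ln, ins in sorted(
        zip(positions.tolist(), lengths.tolist(), is_ins.tolist()), reverse=True
    ):
        if any(lo <= pos <= hi for lo, hi in protected):
            continue
        if ins:
            s = s[:pos] + _random_dna(rng, ln) + s[pos:]
        else:
            s = s[:pos] + s[pos + ln :]
    return s


# --------------------------------------------------------------------------
# population / phenotype / assay generation


def genotype_probabilities(p: float, f: float) -> tuple[float, float, float]:
    """Genotype probabilities under inbreeding coefficient ``f``.

    P(+/+) = p^2 + f p q, P(+/-) = 2 p q (1 - f), P(-/-) = q^2 + f p q,
    clamped to [0, 1] and renormalized.
    """
    q = 1.0 - p
    probs = (p * p + f * p * q, 2 * p * q * (1 - f), q * q + f * p * q)
    if min(probs) < -1e-9:
        raise ValueError(f"infeasible inbreeding coefficient {f} for p={p}")
    probs = np.clip(probs, 0.0, 1.0)
    return tuple(probs / probs.sum())


def make_population(spec: PopulationSpec, seed: int) -> GenotypeCounts:
    """Draw genotype counts for one breed; deterministic given the seed."""
    rng = _rng(seed, _STAGE_POP, _crc(spec.breed))
    probs = genotype_probabilities(spec.p_ins, spec.f)
    counts = rng.multinomial(spec.n, probs)
    return GenotypeCounts(spec.breed, int(counts[0]), int(counts[1]), int(counts[2]))


def make_phenotypes(
    counts: GenotypeCounts, traits: Sequence[TraitSpec], seed: int
) -> pd.DataFrame:
    """Per-animal Gaussian trait values, one genotype group per count cell."""
    rng = _rng(seed, _STAGE_PHENO, _crc(counts.breed))
    rows: dict[str, list] = {"animal_id": [], "genotype": []}
    for t in traits:
        rows[t.name] = []
    idx = 0
    for gi, (g, n) in enumerate(zip(GENOTYPES, counts.as_tuple)):
        for _ in range(n):
            rows["animal_id"].append(f"{counts.breed}_{idx:04d}")
            rows["genotype"].append(g)
            idx += 1
            for t in traits:
                rows[t.name].append(float(rng.normal(t.means[gi], t.sds[gi])))
    return pd.DataFrame(rows)


def make_ct_table(spec: ExpressionSpec, seed: int, sub: int = 0) -> pd.DataFrame:
    """Ct table realizing each group's true fold change in expectation.

    ``ct_target = ct_reference + base_dct - log2(fold/fold_calibrator) + noise``
    so that the 2^-ddCt estimate recovers the specified folds.
    """
    rng = _rng(seed, _STAGE_CT, sub)
    cal_fold = dict((g[0], g[1]) for g in spec.groups)[spec.calibrator]
    rows = []
    i = 0
    for label, fold, n in spec.groups:
        dct_mean = spec.base_dct - np.log2(fold / cal_fold)
        for _ in range(n):
            ct_ref = float(rng.normal(spec.base_ct_reference, spec.reference_sd))
            dct = dct_mean + float(rng.normal(0.0, spec.noise_sd)) if spec.noise_sd else dct_mean
            rows.append(
                {
                    "sample_id": f"s{i:03d}",
                    "group": label,
                    "ct_target": ct_ref + dct,
                    "ct_reference": ct_ref,
                }
            )
            i += 1
    return pd.DataFrame(rows)


def make_luciferase(spec: LuciferaseSpec, seed: int, sub: int = 0) -> pd.DataFrame:
    """Firefly/renilla well readings with construct-specific mean ratios."""
    rng = _rng(seed, _STAGE_LUC, sub)
    rows = []
    for name, ratio, cv, n in spec.constructs:
        for w in range(n):
            renilla = float(rng.normal(1000.0, 50.0))
            renilla = max(renilla, 1.0)
            noise = float(rng.normal(0.0, cv)) if cv else 0.0
            well_ratio = max(ratio * (1.0 + noise), 1e-6)
            rows.append(
                {
                    "construct": name,
                    "firefly": renilla * well_ratio,
                    "renilla": renilla,
                }
            )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# packaged default fixture
#
# Two loci carrying three SINEA1-like insertions of 286/301/321 bp: one in
# intron 1 of a 3-exon gene (reverse orientation), two in introns 2 and 21
# of a 22-exon gene (forward orientation). Six breeds per locus, each
# insertion supported by three carriers, 1% background SNPs.


def default_locus_configs(seed: int) -> list[SimConfig]:
    leprot_like = SimConfig(
        seed=seed,
        gene_name="LEPROT",
        locus_len=15000,
        n_exons=3,
        insertions=(InsertionSpec("SINEA1_286", "intron1", strand="-"),),
        breeds=(
            BreedSpec("Landrace"),
            BreedSpec("Yorkshire"),
            BreedSpec("Meishan", carries=("SINEA1_286",)),
            BreedSpec("Rongchang", carries=("SINEA1_286",)),
            BreedSpec("Wuzhishan", carries=("SINEA1_286",)),
            BreedSpec("Tibetan"),
        ),
    )
    lepr_like = SimConfig(
        seed=seed,
        gene_name="LEPR",
        locus_len=20000,
        n_exons=22,
        exon_len=120,
        insertions=(
            InsertionSpec("SINEA1_301", "intron2", strand="+"),
            InsertionSpec("SINEA1_321", "intron21", strand="+"),
        ),
        breeds=(
            BreedSpec("Landrace", carries=("SINEA1_301",)),
            BreedSpec("Yorkshire", carries=("SINEA1_301", "SINEA1_321")),
            BreedSpec("Meishan", carries=("SINEA1_301",)),
            BreedSpec("Rongchang", carries=("SINEA1_321",)),
            BreedSpec("Wuzhishan",),
            BreedSpec("Tibetan", carries=("SINEA1_321",)),
        ),
    )
    return [leprot_like, lepr_like]


def default_population_specs() -> list[PopulationSpec]:
    return [
        PopulationSpec("Large White", 450, 0.47),
        PopulationSpec("Duroc", 24, 0.4583),
        PopulationSpec("Landrace", 24, 0.1875),
        PopulationSpec("Sujiang", 24, 0.4792, f=0.25),
        PopulationSpec("Jinhua", 24, 0.75, f=0.9),
        PopulationSpec("Rongchang", 24, 0.6458, f=-0.5),
    ]


def default_trait_specs() -> list[TraitSpec]:
    # group dispersions follow sd = sem * sqrt(n) with n = 63/297/90
    ns = np.array([63, 297, 90])
    age_sds = tuple(np.array([1.12, 0.59, 1.08]) * np.sqrt(ns))
    bw_sds = tuple(np.array([1.26, 0.66, 1.20]) * np.sqrt(ns))
    return [
        TraitSpec("age_100kg", (164.81, 160.49, 160.59), age_sds),
        TraitSpec("body_weight", (99.23, 105.10, 104.04), bw_sds),
    ]


def default_phenotype_counts() -> GenotypeCounts:
    return GenotypeCounts("Large White", 63, 297, 90)


def default_expression_spec() -> ExpressionSpec:
    return ExpressionSpec(
        groups=(("+/+", 1.0, 4), ("+/-", 1.2, 4), ("-/-", 2.5, 4)),
        calibrator="+/+",
        noise_sd=0.2,
    )


def default_luciferase_spec() -> LuciferaseSpec:
    return LuciferaseSpec(
        constructs=(
            ("pGL3-basic", 1.0, 0.10, 6),
            ("LEPROT-SINE+", 1.5, 0.10, 6),
            ("LEPROT-SINE-", 3.0, 0.10, 6),
        ),
        control="pGL3-basic",
    )
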