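"""Seeded generators for every input the analysis stages consume.

Each generator inverts the statistical model its consuming stage assumes,
so planted truths can be recovered and compared against the estimate:

* qPCR — Cq values derive from true per-gene relative copy numbers under
  per-gene amplification efficiencies with Gaussian cycle noise;
* ddPCR — droplet partitioning is binomial with the Poisson zero-class
  positivity probability 1 - exp(-lambda);
* pool-seq depth — per-window Poisson counts with a planted amplified
  segment and repeat-masked gaps where coverage collapses;
* RNA-seq — negative-binomial counts with planted over-expressed
  detoxification genes in the focal line;
* field populations — individuals drawn with set structural-haplotype
  frequencies and log-uniform copy numbers over the observed 3-80 range.

Named presets pin the effect sizes characterized for the CCE-cluster
amplification (32-fold pooled CNV, ~80 copies in single individuals,
~50-fold coverage over a ~100-kb segment, seven detoxification
candidates) with fixed seeds, so the whole pipeline is exercisable at desk
scale without any sequencing download. All generators are pure functions
of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .coverage import DepthTrack
from .ddpcr import DropletCount
from .errors import CceampError
from .haplotypes import CLUSTER_GENES

#: Reference (single-copy control) genes used by the qPCR assays.
REFERENCE_GENES = ("AAEL007808", "AAEL005950")

#: The five CCE-cluster genes over-transcribed in the resistant line.
OVEREXPRESSED_CCE = (
    "AAEL015304",
    "AAEL019679",
    "AAEL019678",
    "AAEL005123",
    "AAEL023844",
)


@dataclass(frozen=True)
class QpcrSimSpec:
    """Generating model for a qPCR run: Cq = baseline - log_E(truth) + noise."""

    truths: Mapping[str, Mapping[str, float]]  # sample -> gene -> fold
    efficiencies: Mapping[str, float]
    baseline_cq: Mapping[str, float]
    sigma_cq: float
    replicates: int
    seed: int
    reference_genes: tuple[str, ...] = REFERENCE_GENES
    calibrator_samples: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.sigma_cq < 0:
            raise CceampError("sigma_cq must be >= 0")
        if self.replicates < 1:
            raise CceampError("need >= 1 replicate")
        for s, genes in self.truths.items():
            for g, t in genes.items():
                if t <= 0:
                    raise CceampError(f"truth for {s}/{g} must be > 0")


@dataclass(frozen=True)
class DepthSimSpec:
    """Planted-amplification pool-seq depth model."""

    contig: str = "chr2"
    contig_length: int = 1_000_000
    window: int = 1_000
    mu: float = 40.0
    segments: tuple[tuple[int, int, float], ...] = ()
    mask_segments: tuple[tuple[int, int], ...] = ()
    baseline_contig: str = "chr1"
    baseline_length: int = 1_000_000
    baseline_mu: float = 40.0
    seed: int = 0

    def __post_init__(self) -> None:
        for s, e, f in self.segments:
            if not (0 <= s < e <= self.contig_length) or f <= 0:
                raise CceampError(f"bad segment ({s}, {e}, {f})")
        for s, e in self.mask_segments:
            if not (0 <= s < e <= self.contig_length):
                raise CceampError(f"bad mask segment ({s}, {e})")


@dataclass(frozen=True)
class TranscriptomeSimSpec:
    """Negative-binomial count-matrix model with planted expression folds."""

    n_genes: int = 12_000
    groups: tuple[str, ...] = ("focal", "comparator_1", "comparator_2")
    replicates: int = 4
    baseline_log_mean: float = 3.0  # ln scale of per-gene mean counts
    baseline_log_sd: float = 2.0
    dispersion: float = 0.1
    planted: tuple[tuple[str, Mapping[str, float], str], ...] = ()
    planted_baseline_floor: float = 50.0  # planted genes never start rare
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dispersion <= 0:
            raise CceampError("dispersion must be > 0")
        for gene, folds, _family in self.planted:
            for g, f in folds.items():
                if f <= 0:
                    raise CceampError(f"planted fold for {gene}/{g} must be > 0")


@dataclass(frozen=True)
class PopulationSimSpec:
    """Field-population model with set haplotype frequencies."""

    n_individuals: int = 300
    freq_a: float = 0.1
    freq_b: float = 0.2
    copy_range: tuple[float, float] = (3.0, 80.0)
    cv: float = 0.25
    population_id: str = "pop1"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.freq_a and 0 <= self.freq_b and self.freq_a + self.freq_b <= 1):
            raise CceampError("haplotype frequencies must be >= 0 and sum <= 1")
        lo, hi = self.copy_range
        if not (0 < lo <= hi):
            raise CceampError("copy_range must satisfy 0 < low <= high")


def gen_qpcr(spec: QpcrSimSpec) -> pd.DataFrame:
    """Simulate a long Cq table from true folds.

    Cq(sample, gene) = baseline_cq(gene) - log(truth) / log(E_gene)
                       + N(0, sigma_cq) per replicate.
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    for sample in spec.truths:
        for gene, truth in spec.truths[sample].items():
            e = spec.efficiencies[gene]
            base = spec.baseline_cq[gene]
            cq_true = base - np.log(truth) / np.log(e)
            role = "reference" if gene in spec.reference_genes else "target"
            for rep in range(1, spec.replicates + 1):
                cq = cq_true + rng.normal(0.0, spec.sigma_cq)
                rows.append((sample, gene, role, "SYBR", rep, float(cq), 0.5))
    return pd.DataFrame(
        rows,
        columns=[
            "sample_id",
            "gene_id",
            "gene_role",
            "dye",
            "replicate",
            "cq",
            "template_conc",
        ],
    )


def gen_droplets(
    lambda_true: float,
    n_droplets: int = 20_000,
    seed: int = 0,
    sample_id: str = "sim",
    gene_id: str = "gene",
) -> DropletCount:
    """Binomial droplet partitioning at positivity 1 - exp(-lambda)."""
    if lambda_true < 0:
        raise CceampError("lambda_true must be >= 0")
    rng = np.random.default_rng(seed)
    p_pos = 1.0 - np.exp(-lambda_true)
    n_pos = int(rng.binomial(n_droplets, p_pos))
    return DropletCount(sample_id, gene_id, n_pos, n_droplets - n_pos)


@dataclass(frozen=True)
class DepthSim:
    """Case and control tracks for the focal and baseline contigs."""

    case: DepthTrack
    control: DepthTrack
    case_baseline: DepthTrack
    control_baseline: DepthTrack


def _windows(length: int, width: int) -> tuple[np.ndarray, np.ndarray]:
    starts = np.arange(0, length, width, dtype=np.int64)
    ends = np.minimum(starts + width, length)
    return starts, ends


def gen_depth(spec: DepthSimSpec) -> DepthSim:
    """Simulate windowed Poisson depth with planted amplification and masks.

    Control windows ~ Poisson(mu); case windows ~ Poisson(mu * fold) inside
    planted segments. Masked segments collapse to 5% of mu in both tracks,
    emulating repeat-associated coverage gaps. Baseline contigs are flat.
    """
    rng = np.random.default_rng(spec.seed)
    starts, ends = _windows(spec.contig_length, spec.window)
    mids = (starts + ends) // 2

    fold = np.ones(starts.size)
    for s, e, f in spec.segments:
        fold[(mids >= s) & (mids < e)] = f
    masked = np.zeros(starts.size, dtype=bool)
    for s, e in spec.mask_segments:
        masked[(mids >= s) & (mids < e)] = True

    mu_control = np.where(masked, spec.mu * 0.05, spec.mu)
    mu_case = np.where(masked, spec.mu * 0.05, spec.mu * fold)
    case = DepthTrack(spec.contig, starts, ends, rng.poisson(mu_case).astype(float))
    control = DepthTrack(
        spec.contig, starts, ends, rng.poisson(mu_control).astype(float)
    )

    bstarts, bends = _windows(spec.baseline_length, spec.window)
    case_base = DepthTrack(
        spec.baseline_contig,
        bstarts,
        bends,
        rng.poisson(spec.baseline_mu, bstarts.size).astype(float),
    )
    control_base = DepthTrack(
        spec.baseline_contig,
        bstarts,
        bends,
        rng.poisson(spec.baseline_mu, bstarts.size).astype(float),
    )
    return DepthSim(case, control, case_base, control_base)


def gen_counts(spec: TranscriptomeSimSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate an RNA-seq count matrix and its sample sheet.

    Per-gene baseline means are log-normal; counts are negative-binomial
    with mean = baseline * group fold * sample depth factor and constant
    dispersion (var = m + dispersion * m^2). Depth factors are log-uniform
    in [0.7, 1.4], emulating library-size variation.

    Returns (counts genes x samples, sample sheet with sample_id, group,
    replicate).
    """
    rng = np.random.default_rng(spec.seed)
    gene_ids = [f"GENE{i:05d}" for i in range(spec.n_genes)]
    planted_ids = [g for g, _, _ in spec.planted]
    for i, g in enumerate(planted_ids):
        if g not in gene_ids:
            gene_ids[i] = g  # planted genes replace the first synthetic ids
        else:
            raise CceampError(f"duplicate planted gene {g}")

    base = rng.lognormal(spec.baseline_log_mean, spec.baseline_log_sd, spec.n_genes)
    # keep planted genes comfortably expressed so the floor never hides them
    planted_rows = {g: i for i, g in enumerate(gene_ids) if g in set(planted_ids)}
    for g, row in planted_rows.items():
        base[row] = max(base[row], spec.planted_baseline_floor)

    fold = np.ones((spec.n_genes, len(spec.groups)))
    families = {}
    for g, folds, family in spec.planted:
        row = planted_rows[g]
        families[g] = family
        for j, grp in enumerate(spec.groups):
            fold[row, j] = folds.get(grp, 1.0)

    samples, groups_col, reps_col = [], [], []
    cols = []
    for grp in spec.groups:
        for rep in range(1, spec.replicates + 1):
            sid = f"{grp}_r{rep}"
            samples.append(sid)
            groups_col.append(grp)
            reps_col.append(rep)
            depth = np.exp(rng.uniform(np.log(0.7), np.log(1.4)))
            m = base * fold[:, spec.groups.index(grp)] * depth
            r = 1.0 / spec.dispersion  # NB shape
            counts = rng.negative_binomial(r, r / (r + m))
            cols.append(counts)
    counts = pd.DataFrame(
        np.column_stack(cols), index=pd.Index(gene_ids, name="gene_id"), columns=samples
    )
    sheet = pd.DataFrame(
        {"sample_id": samples, "group": groups_col, "replicate": reps_col}
    )
    return counts, sheet


def gen_population(spec: PopulationSimSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate individual CNV profiles for a mosquito population.

    Each individual draws a structural haplotype (A, B, none) at the set
    frequencies; amplified individuals draw one copy number log-uniformly
    over ``copy_range``, shared by the genes their haplotype spans.
    Unamplified genes sit at N(1, cv); all measured folds then receive
    multiplicative log-normal noise of the same coefficient of variation,
    emulating single-mosquito qPCR error.

    Returns (profile table with one fold column per cluster gene, truth
    table with the drawn haplotype and copy number).
    """
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.copy_range
    sigma_meas = np.sqrt(np.log1p(spec.cv**2))
    hap_genes = {"A": set(CLUSTER_GENES), "B": {"AAEL019678", "AAEL023844"}}
    haps = rng.choice(
        ["A", "B", "none"],
        size=spec.n_individuals,
        p=[spec.freq_a, spec.freq_b, 1.0 - spec.freq_a - spec.freq_b],
    )
    rows, truth_rows = [], []
    for i, hap in enumerate(haps):
        ind = f"{spec.population_id}_ind{i + 1:04d}"
        copies = float(np.exp(rng.uniform(np.log(lo), np.log(hi)))) if hap != "none" else 1.0
        folds = {}
        for g in CLUSTER_GENES:
            true_fold = copies if (hap != "none" and g in hap_genes[hap]) else max(
                rng.normal(1.0, spec.cv), 0.05
            )
            measured = true_fold * np.exp(rng.normal(0.0, sigma_meas))
            folds[g] = float(measured)
        rows.append({"individual_id": ind, "population_id": spec.population_id, **folds})
        truth_rows.append(
            {"individual_id": ind, "haplotype": hap, "copy_number": copies}
        )
    return pd.DataFrame(rows), pd.DataFrame(truth_rows)


def _qpcr_preset(
    sample_truths: Mapping[str, Mapping[str, float]],
    sigma_cq: float,
    replicates: int,
    seed: int,
) -> QpcrSimSpec:
    genes = sorted({g for t in sample_truths.values() for g in t} | set(REFERENCE_GENES))
    truths = {
        s: {g: t.get(g, 1.0) for g in genes} for s, t in sample_truths.items()
    }
    calibrators = ("BORA1", "BORA2", "BORA3")
    for c in calibrators:
        truths[c] = {g: 1.0 for g in genes}
    return QpcrSimSpec(
        truths=truths,
        efficiencies={g: 2.0 for g in genes},
        baseline_cq={g: 24.0 for g in genes},
        sigma_cq=sigma_cq,
        replicates=replicates,
        seed=seed,
        calibrator_samples=calibrators,
    )


def preset(name: str, seed: int | None = None):
    """Named, seed-pinned simulation specs encoding the study effect sizes.

    ``seed`` overrides the pinned seed (for multi-seed property checks).
    """
    if name == "nakh_like":
        spec = DepthSimSpec(
            contig="chr2",
            contig_length=1_000_000,
            window=1_000,
            mu=40.0,
            segments=((450_000, 550_000, 50.0),),
            mask_segments=((470_000, 473_000), (520_000, 523_000)),
            baseline_contig="chr1",
            baseline_length=1_000_000,
            baseline_mu=40.0,
            seed=1177,
        )
    elif name == "g5mala_pool":
        pools = {
            f"POOL{i}": {"AAEL019678": 32.0, "AAEL023844": 32.0, "AAEL005113": 8.0}
            for i in range(1, 8)
        }
        spec = _qpcr_preset(pools, sigma_cq=0.15, replicates=2, seed=2255)
    elif name == "high_copy_individual":
        spec = _qpcr_preset(
            {"IND1": {"AAEL023844": 80.0}}, sigma_cq=0.2, replicates=1, seed=3380
        )
    elif name == "mala_transcriptome":
        planted: list[tuple[str, Mapping[str, float], str]] = [
            (g, {"focal": 10.0}, "CCE") for g in OVEREXPRESSED_CCE
        ]
        planted.append(("AAEL006818", {"focal": 13.0}, "GST"))
        planted.append(("AAEL010158", {"focal": 8.0}, "P450"))
        # decoys elevated versus one comparator only: excluded by the
        # both-comparators rule
        for i in range(20):
            planted.append(
                (f"DECOY{i:03d}", {"focal": 10.0, "comparator_2": 10.0}, "decoy")
            )
        # each library pools 25 females, so between-library dispersion is far
        # below single-individual biological variability; detox transcripts
        # are abundant even in susceptible lines
        spec = TranscriptomeSimSpec(
            planted=tuple(planted),
            dispersion=0.01,
            planted_baseline_floor=2_000.0,
            seed=4412,
        )
    else:
        raise CceampError(f"unknown preset {name!r}")
    if seed is not None:
        spec = replace(spec, seed=int(seed))
    return spec


def preset_truth(name: str) -> dict:
    """Planted parameters of a preset, for test harnesses and sidecars."""
    if name == "nakh_like":
        return {"segment": (450_000, 550_000), "fold": 50.0, "length_kb": 100.0}
    if name == "g5mala_pool":
        return {"AAEL019678": 32.0, "AAEL023844": 32.0, "AAEL005113": 8.0}
    if name == "high_copy_individual":
        return {"AAEL023844": 80.0}
    if name == "mala_transcriptome":
        spec = preset("mala_transcriptome")
        return {
            "over_candidates": tuple(
                g for g, folds, fam in spec.planted if fam != "decoy"
            )
        }
    raise CceampError(f"unknown preset {name!r}")
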