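"""Positivity calling, structural-haplotype assignment and population summaries.

The amplified carboxylesterase (CCE) cluster on chromosome 2 is assayed
through three genes spanning it: AAEL019678, AAEL023844 (formerly CCEAE3A)
and AAEL005113 (CCEAE1A). An individual is positive when any assayed
cluster gene shows a copy-number fold >= 2.5 versus the susceptible
calibrator line — a threshold above qPCR technical variation (<2-fold in
negative controls). Two structural haplotypes are distinguished:

* haplotype A — all three genes amplified;
* haplotype B — AAEL019678 and AAEL023844 amplified, CCEAE1A not.

Positive individuals matching neither pattern are reported as "other",
covering additional structural haplotypes segregating in the field.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import CceampError, EmptyPopulationError

#: Cluster genes required for full haplotype assignment, 5' to 3'.
CLUSTER_GENES = ("AAEL019678", "AAEL023844", "AAEL005113")

#: Default positivity threshold, fold versus the calibrator line.
POSITIVITY_THRESHOLD = 2.5


@dataclass(frozen=True)
class GeneCnvProfile:
    """Per-individual CNV folds, gene_id -> fold vs calibrator."""

    individual_id: str
    population_id: str
    folds: Mapping[str, float]


@dataclass(frozen=True)
class HaplotypeCall:
    individual_id: str
    positive: bool
    haplotype: str  # A, B, other, negative
    flag: str | None = None


@dataclass(frozen=True)
class PopulationSummary:
    population_id: str
    n: int
    n_positive: int
    prevalence: float  # percent of individuals
    freq_a: float  # percent of all individuals
    freq_b: float
    freq_other: float
    share_a_among_positive: float | None
    share_b_among_positive: float | None
    mean_fold: Mapping[str, float] = field(default_factory=dict)


def classify(
    profile: GeneCnvProfile, threshold: float = POSITIVITY_THRESHOLD
) -> HaplotypeCall:
    """Call positivity and structural haplotype from a CNV profile.

    Positive iff any assayed cluster gene fold >= threshold (inclusive).
    Haplotype A iff all three cluster genes >= threshold; B iff AAEL019678
    and AAEL023844 >= threshold and AAEL005113 < threshold; any other
    positive pattern is "other". Profiles missing cluster genes are still
    callable for positivity but the haplotype is "other" with a
    ``partial-profile`` flag.
    """
    if threshold <= 1:
        raise CceampError(f"positivity threshold must be > 1, got {threshold}")
    present = {g: profile.folds[g] for g in CLUSTER_GENES if g in profile.folds}
    if not present:
        raise CceampError(
            f"{profile.individual_id}: no cluster gene fold in profile"
        )
    if any(f < 0 for f in present.values()):
        raise CceampError(f"{profile.individual_id}: negative fold")
    positive = any(f >= threshold for f in present.values())
    if len(present) < len(CLUSTER_GENES):
        hap = "other" if positive else "negative"
        return HaplotypeCall(profile.individual_id, positive, hap, "partial-profile")
    up = {g: present[g] >= threshold for g in CLUSTER_GENES}
    if not positive:
        hap = "negative"
    elif all(up.values()):
        hap = "A"
    elif up["AAEL019678"] and up["AAEL023844"] and not up["AAEL005113"]:
        hap = "B"
    else:
        hap = "other"
    return HaplotypeCall(profile.individual_id, positive, hap)


def summarize_population(
    calls: Sequence[HaplotypeCall], profiles: Sequence[GeneCnvProfile]
) -> PopulationSummary:
    """Prevalence, haplotype frequencies and mean folds for one population.

    Frequencies are percentages of all genotyped individuals; shares among
    positives are additionally reported (None when nothing is positive).
    ``mean_fold`` averages each gene's fold over positive individuals only.
    """
    if not calls:
        raise EmptyPopulationError("no haplotype calls to summarize")
    by_id = {p.individual_id: p for p in profiles}
    pop_ids = {p.population_id for p in profiles}
    pop_id = pop_ids.pop() if len(pop_ids) == 1 else "+".join(sorted(pop_ids))

    n = len(calls)
    counts = {"A": 0, "B": 0, "other": 0, "negative": 0}
    for c in calls:
        counts[c.haplotype] += 1
    n_pos = n - counts["negative"]

    mean_fold: dict[str, float] = {}
    pos_profiles = [
        by_id[c.individual_id] for c in calls if c.positive and c.individual_id in by_id
    ]
    genes = sorted({g for p in pos_profiles for g in p.folds})
    for g in genes:
        vals = [p.folds[g] for p in pos_profiles if g in p.folds]
        if vals:
            mean_fold[g] = float(np.mean(vals))

    pct = lambda k: 100.0 * k / n  # noqa: E731
    return PopulationSummary(
        population_id=pop_id,
        n=n,
        n_positive=n_pos,
        prevalence=pct(n_pos),
        freq_a=pct(counts["A"]),
        freq_b=pct(counts["B"]),
        freq_other=pct(counts["other"]),
        share_a_among_positive=100.0 * counts["A"] / n_pos if n_pos else None,
        share_b_among_positive=100.0 * counts["B"] / n_pos if n_pos else None,
        mean_fold=mean_fold,
    )


def profiles_from_folds(
    folds: pd.DataFrame, populations: Mapping[str, str] | None = None
) -> list[GeneCnvProfile]:
    """Pivot a long fold table (sample_id, gene_id, fold) into profiles."""
    required = {"sample_id", "gene_id", "fold"}
    if not required.issubset(folds.columns):
        raise CceampError(f"fold table needs columns {sorted(required)}")
    wide = folds.pivot_table(index="sample_id", columns="gene_id", values="fold")
    out = []
    for ind, row in wide.iterrows():
        pop = populations.get(ind, "all") if populations else "all"
        out.append(
            GeneCnvProfile(str(ind), pop, {g: v for g, v in row.items() if pd.notna(v)})
        )
    return out


def genotype_table(
    profiles: Iterable[GeneCnvProfile], threshold: float = POSITIVITY_THRESHOLD
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Classify every profile and summarize per population.

    Returns (calls table, per-population summary table). Percentages are
    carried at full precision; round only for display.
    """
    profiles = list(profiles)
    calls = {p.individual_id: classify(p, threshold) for p in profiles}
    gene_cols = sorted({g for p in profiles for g in p.folds})
    call_rows = []
    for p in profiles:
        c = calls[p.individual_id]
        row = {
            "individual_id": p.individual_id,
            "population_id": p.population_id,
            **{g: p.folds.get(g, np.nan) for g in gene_cols},
            "positive": c.positive,
            "haplotype": c.haplotype,
            "flag": c.flag,
        }
        call_rows.append(row)
    calls_df = pd.DataFrame(call_rows)

    summaries = []
    for pop in sorted({p.population_id for p in profiles}):
        pop_profiles = [p for p in profiles if p.population_id == pop]
        s = summarize_population(
            [calls[p.individual_id] for p in pop_profiles], pop_profiles
        )
        summaries.append(
            {
                "population_id": s.population_id,
                "n": s.n,
                "n_positive": s.n_positive,
                "prevalence": s.prevalence,
                "freq_A": s.freq_a,
                "freq_B": s.freq_b,
                "freq_other": s.freq_other,
                "share_A_among_positive": s.share_a_among_positive,
                "share_B_among_positive": s.share_b_among_positive,
                **{f"mean_fold_{g}": s.mean_fold.get(g, np.nan) for g in gene_cols},
            }
        )
    return calls_df, pd.DataFrame(summaries)
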