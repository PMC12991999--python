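"""Per-repertoire diversity and clonality statistics, and between-group tests.

All statistics assume the repertoire has been depth-normalized (see
:mod:`tcrgvhd.normalize`) so that counts are comparable across samples.

Implemented measures
--------------------
richness
    number of unique clonotypes.
Chao1
    nonparametric richness estimator ``S_obs + f1^2 / (2 f2)`` from the
    singleton (f1) and doubleton (f2) counts, with the bias-corrected
    fallback ``S_obs + f1 (f1 - 1) / 2`` when no doubletons exist.
Inverse Simpson index (ISI)
    ``1 / sum(p_i^2)`` — an evenness-weighted effective clonotype number.
expanded clonotypes (z > 2)
    clone counts are z-scored (sample SD, n-1 denominator by default) and
    those strictly above the threshold counted.
plus low-frequency clone counts, rank-band read masses, frequency-band
richness, CDR3 length distributions and V/J segment usage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .repertoire import ConfigError, Repertoire

logger = logging.getLogger(__name__)

RANK_BANDS = (("top1_10", 1, 10), ("top11_100", 11, 100), ("top101_1000", 101, 1000))


def _sorted_counts(repertoire: Repertoire) -> np.ndarray:
    """Counts sorted descending with deterministic tie-breaks
    (lexicographic CDR3, then V gene)."""
    df = repertoire.clonotypes
    order = np.lexsort(
        (df["v_gene"].to_numpy(), df["cdr3_aa"].to_numpy(), -df["count"].to_numpy())
    )
    return df["count"].to_numpy()[order]


def richness(repertoire: Repertoire) -> int:
    """Number of unique clonotypes with at least one read."""
    return repertoire.richness


def chao1(repertoire: Repertoire) -> float:
    counts = repertoire.counts()
    s_obs = int((counts >= 1).sum())
    f1 = int((counts == 1).sum())
    f2 = int((counts == 2).sum())
    if f2 > 0:
        return s_obs + f1 * f1 / (2.0 * f2)
    return s_obs + f1 * (f1 - 1) / 2.0


def inverse_simpson(repertoire: Repertoire) -> float:
    p = repertoire.frequencies()
    return 1.0 / float(np.sum(p * p))


def expanded_count_z2(
    repertoire: Repertoire, z_threshold: float = 2.0, population_sd: bool = False
) -> int:
    """Number of clonotypes whose z-scored count strictly exceeds the
    threshold.  Frequencies would give identical z-scores (affine
    invariance), so counts are used directly."""
    counts = repertoire.counts().astype(float)
    if counts.size < 2:
        logger.warning("%s: <2 clonotypes, no expansion measurable", repertoire.sample_id)
        return 0
    sd = counts.std(ddof=0 if population_sd else 1)
    if sd == 0:
        logger.warning("%s: constant counts, no expansion measurable", repertoire.sample_id)
        return 0
    z = (counts - counts.mean()) / sd
    return int((z > z_threshold).sum())


def low_freq_count(repertoire: Repertoire, max_count: int = 100) -> int:
    """Number of clonotypes with read count strictly below ``max_count``."""
    return int((repertoire.counts() < max_count).sum())


def rank_band_mass(repertoire: Repertoire) -> dict[str, float]:
    """Fraction of reads held by abundance ranks 1-10, 11-100, 101-1000 and
    beyond."""
    counts = _sorted_counts(repertoire).astype(float)
    total = counts.sum()
    out = {}
    for name, lo, hi in RANK_BANDS:
        out[name] = float(counts[lo - 1: hi].sum() / total)
    out["rest"] = float(counts[1000:].sum() / total)
    return out


def freq_band_richness(
    repertoire: Repertoire, boundary: float = 0.001
) -> dict[str, int]:
    """Clonotype counts in the low (0, boundary] and high (boundary, 1]
    frequency bands; a clone exactly at the boundary falls in the low band."""
    p = repertoire.frequencies()
    low = int((p <= boundary).sum())
    return {"low": low, "high": int(p.size - low)}


def cdr3_length_distribution(
    repertoire: Repertoire, weighting: str = "reads"
) -> dict[int, float]:
    df = repertoire.clonotypes
    lengths = df["cdr3_aa"].str.len()
    w = df["count"] if weighting == "reads" else pd.Series(1.0, index=df.index)
    if weighting not in ("reads", "clonotypes"):
        raise ConfigError(f"unknown weighting {weighting!r}")
    g = w.groupby(lengths).sum()
    g = g / g.sum()
    return {int(k): float(v) for k, v in g.sort_index().items()}


def gene_usage(
    repertoire: Repertoire, segment: str = "V", weighting: str = "reads"
) -> dict[str, float]:
    """Relative usage of V or J gene segments (allele-stripped at I/O time)."""
    if segment not in ("V", "J"):
        raise ConfigError(f"segment must be 'V' or 'J' (got {segment!r})")
    if weighting not in ("reads", "clonotypes"):
        raise ConfigError(f"unknown weighting {weighting!r}")
    df = repertoire.clonotypes
    col = "v_gene" if segment == "V" else "j_gene"
    w = df["count"] if weighting == "reads" else pd.Series(1.0, index=df.index)
    g = w.groupby(df[col]).sum()
    g = g / g.sum()
    return {str(k): float(v) for k, v in g.sort_index().items()}


@dataclass
class DiversityResult:
    """Every per-sample statistic the pipeline reports."""

    sample_id: str
    richness: int
    chao1: float
    inverse_simpson: float
    expanded_count_z2: int
    expanded_mass_z2: float
    low_freq_count: int
    rank_band_mass: dict[str, float]
    freq_band_richness: dict[str, int]
    cdr3_length_dist: dict[int, float]
    v_usage: dict[str, float]
    j_usage: dict[str, float]


def diversity_profile(repertoire: Repertoire) -> DiversityResult:
    counts = repertoire.counts().astype(float)
    total = counts.sum()
    n_exp = expanded_count_z2(repertoire)
    if n_exp and counts.size >= 2:
        sd = counts.std(ddof=1)
        z = (counts - counts.mean()) / sd
        exp_mass = float(counts[z > 2.0].sum() / total)
    else:
        exp_mass = 0.0
    return DiversityResult(
        sample_id=repertoire.sample_id,
        richness=richness(repertoire),
        chao1=chao1(repertoire),
        inverse_simpson=inverse_simpson(repertoire),
        expanded_count_z2=n_exp,
        expanded_mass_z2=exp_mass,
        low_freq_count=low_freq_count(repertoire),
        rank_band_mass=rank_band_mass(repertoire),
        freq_band_richness=freq_band_richness(repertoire),
        cdr3_length_dist=cdr3_length_distribution(repertoire),
        v_usage=gene_usage(repertoire, "V"),
        j_usage=gene_usage(repertoire, "J"),
    )


# -- between-group tests ----------------------------------------------------


@dataclass(frozen=True)
class GroupTestResult:
    test: str
    statistic: float
    p: float
    n_per_group: tuple[int, ...]


TESTS = ("wilcoxon_rank_sum", "wilcoxon_signed_rank", "ks_two_sample", "fisher_exact")


def compare_groups(
    values_by_group: Mapping[str, Sequence[float]] | Sequence[Sequence[float]],
    test: str = "wilcoxon_rank_sum",
) -> GroupTestResult:
    """Two-sided comparison of two groups of per-sample values.

    ``fisher_exact`` expects a 2x2 integer table instead of value vectors.
    All tests delegate to scipy; degenerate all-equal inputs return p = 1.
    """
    if test == "fisher_exact":
        table = np.asarray(values_by_group, dtype=np.int64)
        if table.shape != (2, 2):
            raise ConfigError("fisher_exact requires a 2x2 integer table")
        odds, p = stats.fisher_exact(table, alternative="two-sided")
        return GroupTestResult(test, float(odds), float(p), tuple(table.sum(axis=1)))

    if isinstance(values_by_group, Mapping):
        groups = [np.asarray(v, dtype=float) for v in values_by_group.values()]
    else:
        groups = [np.asarray(v, dtype=float) for v in values_by_group]
    if len(groups) != 2:
        raise ConfigError("exactly two groups are required")
    a, b = groups
    if len(a) < 2 or len(b) < 2:
        raise ConfigError("each group needs at least 2 values")
    if np.all(a == a[0]) and np.all(b == b[0]) and a[0] == b[0]:
        return GroupTestResult(test, 0.0, 1.0, (len(a), len(b)))
    if test == "wilcoxon_rank_sum":
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
    elif test == "wilcoxon_signed_rank":
        if len(a) != len(b):
            raise ConfigError("signed-rank test requires paired equal-length vectors")
        res = stats.wilcoxon(a, b, alternative="two-sided")
    elif test == "ks_two_sample":
        res = stats.ks_2samp(a, b, alternative="two-sided")
    else:
        raise ConfigError(f"unknown test {test!r}; expected one of {TESTS}")
    return GroupTestResult(test, float(res.statistic), float(res.pvalue), (len(a), len(b)))


def age_richness_correlation(cohort: Sequence[Repertoire]) -> GroupTestResult:
    """Spearman rank correlation between donor age and normalized richness
    (samples without a donor age are skipped)."""
    pairs = [(r.donor_age, r.richness) for r in cohort if r.donor_age is not None]
    if len(pairs) < 3:
        raise ConfigError("need at least 3 samples with donor_age")
    age, rich = zip(*pairs)
    rho, p = stats.spearmanr(age, rich)
    return GroupTestResult("spearman", float(rho), float(p), (len(pairs),))
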