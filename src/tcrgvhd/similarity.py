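"""Cross-sample sharing of specificity groups and library classification.

Each sample is reduced to its *group-membership profile* — the set of
specificity groups in which it has at least one member clonotype.  Pairwise
overlap of profiles is quantified by the Jaccard index
``|A ∩ B| / |A ∪ B|`` and a pre-symptomatic query sample is classified by
comparing its similarity to an active-GVHD library versus a no-GVHD library.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .gliph import MotifGroup
from .repertoire import ConfigError, Repertoire

logger = logging.getLogger(__name__)


def membership_profiles(
    groups: Sequence[MotifGroup],
    cohort: Sequence[Repertoire] | Sequence[str],
) -> dict[str, frozenset]:
    """One profile per sample (samples in no group get an empty set, retained)."""
    sample_ids = [r.sample_id if isinstance(r, Repertoire) else str(r) for r in cohort]
    profile: dict[str, set] = {s: set() for s in sample_ids}
    for g in groups:
        for s in g.sample_ids:
            if s in profile:
                profile[s].add(g.group_id)
    empty = [s for s, gs in profile.items() if not gs]
    if empty:
        logger.warning("samples with no group membership: %s", empty)
    return {s: frozenset(gs) for s, gs in profile.items()}


def jaccard(a: frozenset | set, b: frozenset | set) -> float:
    """|a ∩ b| / |a ∪ b|; two empty sets give 0 by convention (an
    uninformative sample should not look similar to anything)."""
    union = len(a | b)
    if union == 0:
        return 0.0
    return len(a & b) / union


@dataclass
class SimilarityMatrix:
    sample_ids: list[str]
    values: np.ndarray  # symmetric, diagonal 1, entries in [0, 1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.sample_ids)

    def pair_values(self, ids_a: Sequence[str], ids_b: Optional[Sequence[str]] = None
                    ) -> list[float]:
        """Off-diagonal values within ``ids_a`` (ids_b None) or across the two
        id sets."""
        idx = {s: i for i, s in enumerate(self.sample_ids)}
        vals = []
        if ids_b is None:
            ids = [s for s in ids_a if s in idx]
            for i, s in enumerate(ids):
                for t in ids[i + 1:]:
                    vals.append(float(self.values[idx[s], idx[t]]))
        else:
            for s in ids_a:
                for t in ids_b:
                    if s in idx and t in idx and s != t:
                        vals.append(float(self.values[idx[s], idx[t]]))
        return vals


def pairwise_similarity(profiles: Mapping[str, frozenset]) -> SimilarityMatrix:
    """Jaccard over all unordered sample pairs, samples ordered by id."""
    if len(profiles) < 2:
        raise ConfigError("need at least 2 profiles")
    ids = sorted(profiles)
    n = len(ids)
    values = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            v = jaccard(profiles[ids[i]], profiles[ids[j]])
            values[i, j] = values[j, i] = v
    return SimilarityMatrix(ids, values)


@dataclass(frozen=True)
class ContrastResult:
    contrast: str
    median_a: float
    median_b: float
    p: float
    n_a: int
    n_b: int


def group_contrast(
    matrix: SimilarityMatrix, labels: Mapping[str, str]
) -> list[ContrastResult]:
    """Rank-sum contrasts of within-group pair similarities (and each group's
    within-pairs against cross-group pairs).  Labels with fewer than two
    samples are skipped with a warning."""
    by_label: dict[str, list[str]] = {}
    for s in matrix.sample_ids:
        if s in labels:
            by_label.setdefault(labels[s], []).append(s)
    usable = {}
    for lab, ids in sorted(by_label.items()):
        if len(ids) < 2:
            logger.warning("label %s has <2 samples; contrast skipped", lab)
        else:
            usable[lab] = ids
    pools = {lab: matrix.pair_values(ids) for lab, ids in usable.items()}
    labs = sorted(usable)
    cross = []
    for i, la in enumerate(labs):
        for lb in labs[i + 1:]:
            cross.extend(matrix.pair_values(usable[la], usable[lb]))
    results = []

    def _contrast(name, va, vb):
        if len(va) < 2 or len(vb) < 2:
            return
        if set(va) == set(vb) and len(set(va)) == 1:
            p = 1.0
        else:
            p = float(stats.mannwhitneyu(va, vb, alternative="two-sided").pvalue)
        results.append(
            ContrastResult(name, float(np.median(va)), float(np.median(vb)), p,
                           len(va), len(vb))
        )

    for i, la in enumerate(labs):
        for lb in labs[i + 1:]:
            _contrast(f"within_{la}_vs_within_{lb}", pools[la], pools[lb])
    for la in labs:
        _contrast(f"within_{la}_vs_cross", pools[la], cross)
    return results


@dataclass(frozen=True)
class ClassificationResult:
    label: str  # "GVHD" | "NO_GVHD" | "indeterminate"
    score_gvhd: float
    score_nogvhd: float
    p: float


def classify_query(
    query_profile: frozenset,
    gvhd_profiles: Mapping[str, frozenset] | Sequence[frozenset],
    nogvhd_profiles: Mapping[str, frozenset] | Sequence[frozenset],
) -> ClassificationResult:
    """Label a query by its median Jaccard similarity to each library.

    The median is the primary score (robust to one highly similar relative);
    when the medians tie — common for sparse profiles — the mean breaks the
    tie, and only a full tie yields ``indeterminate``.  The p-value is a
    two-sided rank-sum comparison of the two sets of query-vs-library
    similarities.
    """
    gv = list(gvhd_profiles.values() if isinstance(gvhd_profiles, Mapping)
              else gvhd_profiles)
    ng = list(nogvhd_profiles.values() if isinstance(nogvhd_profiles, Mapping)
              else nogvhd_profiles)
    if len(gv) < 2 or len(ng) < 2:
        raise ConfigError("each library needs at least 2 profiles")
    if len(query_profile) == 0:
        logger.warning("empty query profile; classification indeterminate")
        return ClassificationResult("indeterminate", 0.0, 0.0, 1.0)
    sims_gv = [jaccard(query_profile, p) for p in gv]
    sims_ng = [jaccard(query_profile, p) for p in ng]
    med_gv, med_ng = float(np.median(sims_gv)), float(np.median(sims_ng))
    if set(sims_gv) == set(sims_ng) and len(set(sims_gv)) == 1:
        p = 1.0
    else:
        p = float(stats.mannwhitneyu(sims_gv, sims_ng, alternative="two-sided").pvalue)
    if med_gv > med_ng:
        label = "GVHD"
    elif med_ng > med_gv:
        label = "NO_GVHD"
    else:
        mean_gv, mean_ng = float(np.mean(sims_gv)), float(np.mean(sims_ng))
        if mean_gv > mean_ng:
            label = "GVHD"
        elif mean_ng > mean_gv:
            label = "NO_GVHD"
        else:
            label = "indeterminate"
    return ClassificationResult(label, med_gv, med_ng, p)
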