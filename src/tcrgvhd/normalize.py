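"""Depth normalization: down-sample every repertoire to a common number of
productive reads before any diversity statistic is computed.

Down-sampling is a without-replacement draw (multivariate hypergeometric over
the clonotype counts): it emulates resampling of the actual reads, so the
output depth is hit exactly, no clonotype ever gains reads, and no new
clonotype appears.  A faster multinomial (with-replacement) mode is available
behind a flag but is not the default.
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence

import numpy as np

from .repertoire import ConfigError, Repertoire
from .simulate import subject_seed

logger = logging.getLogger(__name__)

DEFAULT_TARGET_READS = 1_000_000


def downsample_repertoire(
    repertoire: Repertoire,
    target_reads: int,
    seed: int = 0,
    method: str = "hypergeometric",
) -> Repertoire:
    """Down-sample to exactly ``target_reads`` reads (without replacement).

    A repertoire already at or below the target is returned unchanged with a
    warning; clonotypes whose count reaches zero are removed.
    """
    if target_reads <= 0:
        raise ConfigError(f"target_reads must be positive (got {target_reads})")
    total = repertoire.total_reads
    if total <= target_reads:
        if total < target_reads:
            logger.warning(
                "%s: %d reads below target %d; returned unchanged",
                repertoire.sample_id, total, target_reads,
            )
        return repertoire
    rng = np.random.default_rng(seed)
    counts = repertoire.counts()
    if method == "hypergeometric":
        new = rng.multivariate_hypergeometric(counts, target_reads, method="marginals")
    elif method == "multinomial":
        new = rng.multinomial(target_reads, counts / counts.sum())
    else:
        raise ConfigError(f"unknown downsampling method {method!r}")
    return repertoire.with_counts(new)


def normalize_cohort(
    cohort: Sequence[Repertoire],
    target_reads: Optional[int] = DEFAULT_TARGET_READS,
    seed: int = 0,
    policy: str = "fixed",
    method: str = "hypergeometric",
) -> tuple[list[Repertoire], dict[str, bool]]:
    """Down-sample every sample to a common depth.

    ``policy='fixed'`` uses ``target_reads`` (default 1,000,000 productive
    reads); ``policy='min'`` uses the smallest depth in the cohort.  Each
    sample draws from a seed derived from ``(seed, sample_id)`` so results do
    not depend on cohort ordering.  Samples below the target are retained and
    flagged (``True`` in the returned mapping) rather than dropped — exclusion
    is the analyst's decision.
    """
    if policy == "min":
        target = min(r.total_reads for r in cohort)
    elif policy == "fixed":
        if target_reads is None:
            raise ConfigError("policy 'fixed' requires target_reads")
        target = int(target_reads)
    else:
        raise ConfigError(f"unknown depth policy {policy!r}")
    out: list[Repertoire] = []
    below: dict[str, bool] = {}
    for rep in cohort:
        sseq = subject_seed(seed, f"downsample/{rep.sample_id}")
        rep_seed = int(sseq.generate_state(1)[0] % 2**31)
        below[rep.sample_id] = rep.total_reads < target
        out.append(downsample_repertoire(rep, target, seed=rep_seed, method=method))
    if any(below.values()):
        logger.warning(
            "samples below target depth %d: %s",
            target, sorted(s for s, b in below.items() if b),
        )
    return out, below
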