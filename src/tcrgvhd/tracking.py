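"""Longitudinal clonotype tracking and between-stage repertoire overlap.

The top-N clonotypes of a chosen reference stage (N = 100 by default) are
looked up in every other stage of the same subject, yielding a
clonotype-by-stage frequency matrix with presence/absence status.  Overall
between-stage similarity uses the Morisita–Horn index

    C = 2 Σ x_i y_i / ((d_x + d_y) X Y),   d_x = Σ x_i² / X²,

an abundance-weighted overlap in [0, 1] that is invariant to sequencing
depth (the classical count-based Morisita variant is available behind a
flag).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .repertoire import ConfigError, Repertoire


def top_n_clonotypes(repertoire: Repertoire, n: int = 100) -> list[tuple[str, str, str]]:
    """Top-n clonotype keys by count (ties broken lexicographically by CDR3,
    then V gene); all keys when the repertoire holds fewer than n."""
    df = repertoire.clonotypes
    order = np.lexsort(
        (df["v_gene"].to_numpy(), df["cdr3_aa"].to_numpy(), -df["count"].to_numpy())
    )
    top = df.iloc[order[:n]]
    return list(zip(top["cdr3_aa"], top["v_gene"], top["j_gene"]))


@dataclass
class TrackingTable:
    subject_id: str
    reference_stage: int
    clonotype_keys: list[tuple[str, str, str]]
    stages: list[int]
    frequencies: np.ndarray  # clonotype x stage, in [0, 1]
    statuses: np.ndarray  # bool, True = present

    def to_frame(self) -> pd.DataFrame:
        """Long-format table for external plotting."""
        rows = []
        for i, key in enumerate(self.clonotype_keys):
            for j, st in enumerate(self.stages):
                rows.append(
                    (
                        self.subject_id, self.reference_stage, *key, st,
                        self.frequencies[i, j],
                        "present" if self.statuses[i, j] else "absent",
                    )
                )
        return pd.DataFrame(
            rows,
            columns=[
                "subject_id", "reference_stage", "cdr3_aa", "v_gene", "j_gene",
                "stage", "frequency", "status",
            ],
        )


def track(
    subject_repertoires: Mapping[int, Repertoire],
    reference_stage: int,
    n: int = 100,
) -> TrackingTable:
    """Frequencies of the reference stage's top-n clonotypes at every stage
    (0 and 'absent' where a clone is not seen)."""
    if len(subject_repertoires) < 2:
        raise ConfigError("need repertoires from at least 2 stages")
    if reference_stage not in subject_repertoires:
        raise ConfigError(f"unknown reference stage {reference_stage}")
    ref = subject_repertoires[reference_stage]
    keys = top_n_clonotypes(ref, n)
    stages = sorted(subject_repertoires)
    freqs = np.zeros((len(keys), len(stages)))
    status = np.zeros((len(keys), len(stages)), dtype=bool)
    for j, st in enumerate(stages):
        rep = subject_repertoires[st]
        total = rep.total_reads
        lookup = {
            k: c for k, c in zip(rep.keys(), rep.counts())
        }
        for i, key in enumerate(keys):
            c = lookup.get(key, 0)
            freqs[i, j] = c / total
            status[i, j] = c > 0
    return TrackingTable(
        subject_id=ref.subject_id,
        reference_stage=reference_stage,
        clonotype_keys=keys,
        stages=stages,
        frequencies=freqs,
        statuses=status,
    )


def morisita(x, y, classical: bool = False) -> float:
    """Morisita–Horn overlap of two count vectors over the same key union.

    ``classical=True`` uses the original count-based Morisita index (requires
    integer counts and totals of at least 2).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ConfigError("count vectors must share the clonotype key union")
    X, Y = x.sum(), y.sum()
    if X <= 0 or Y <= 0:
        raise ConfigError("zero-total count vector")
    cross = float(np.sum(x * y))
    if classical:
        if X < 2 or Y < 2:
            raise ConfigError("classical Morisita needs totals >= 2")
        d_x = float(np.sum(x * (x - 1))) / (X * (X - 1))
        d_y = float(np.sum(y * (y - 1))) / (Y * (Y - 1))
    else:
        d_x = float(np.sum(x * x)) / (X * X)
        d_y = float(np.sum(y * y)) / (Y * Y)
    if cross == 0:
        return 0.0
    return 2.0 * cross / ((d_x + d_y) * X * Y)


def _aligned_counts(reps: Sequence[Repertoire]) -> np.ndarray:
    keys = sorted({k for r in reps for k in r.keys()})
    index = {k: i for i, k in enumerate(keys)}
    mat = np.zeros((len(reps), len(keys)))
    for row, rep in enumerate(reps):
        for k, c in zip(rep.keys(), rep.counts()):
            mat[row, index[k]] = c
    return mat


def stage_similarity(
    subject_repertoires: Mapping[int, Repertoire], classical: bool = False
) -> tuple[list[int], np.ndarray]:
    """Morisita(-Horn) similarity for all stage pairs of one subject
    (symmetric, diagonal 1)."""
    if len(subject_repertoires) < 2:
        raise ConfigError("need at least 2 stages")
    stages = sorted(subject_repertoires)
    mat = _aligned_counts([subject_repertoires[s] for s in stages])
    n = len(stages)
    out = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = morisita(mat[i], mat[j], classical=classical)
    return stages, out
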