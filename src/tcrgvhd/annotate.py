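"""Intersection of high-frequency clones with annotated CDR3 databases.

High-frequency clones (frequency strictly above 0.01% of reads by default)
are matched exactly — whole CDR3 string, case-normalized, optionally
requiring the V gene to agree — against annotation sets such as
tissue-derived GVHD clone lists or pathogen-specific entries from a VDJdb
export.  The per-sample score is the number of matched clones and their
summed read frequency; group differences are assessed per annotation set
with a rank-sum test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from .diversity import compare_groups
from .repertoire import AnnotationRecord, Clonotype, ConfigError, Repertoire

logger = logging.getLogger(__name__)


def high_frequency_clones(
    repertoire: Repertoire, floor: float = 0.0001
) -> list[Clonotype]:
    """Clonotypes whose frequency strictly exceeds ``floor`` (default 0.01%)."""
    df = repertoire.clonotypes
    total = repertoire.total_reads
    keep = df["count"] / total > floor
    return [
        Clonotype(r.cdr3_aa, r.v_gene, r.j_gene, int(r.count), repertoire.chain)
        for r in df[keep].itertuples()
    ]


@dataclass
class SharedCloneScore:
    n_shared: int
    summed_frequency: float
    matched: list[Clonotype]
    by_species: dict[str, float]  # summed frequency per antigen species


def shared_clone_score(
    repertoire: Repertoire,
    annotations: Sequence[AnnotationRecord],
    match_on: str = "cdr3",
    floor: float = 0.0001,
) -> SharedCloneScore:
    """Intersect the repertoire's high-frequency clones with an annotation set
    and sum the matched read frequencies."""
    if match_on not in ("cdr3", "cdr3_v"):
        raise ConfigError(f"unknown match_on {match_on!r}")
    if not annotations:
        logger.warning("%s: empty annotation set", repertoire.sample_id)
        return SharedCloneScore(0, 0.0, [], {})
    total = repertoire.total_reads
    species_by_key: dict = {}
    for rec in annotations:
        key = rec.cdr3_aa.upper() if match_on == "cdr3" else (
            rec.cdr3_aa.upper(), rec.v_gene or "")
        species_by_key.setdefault(key, set()).add(rec.antigen_species)
    matched: list[Clonotype] = []
    by_species: dict[str, float] = {}
    for clone in high_frequency_clones(repertoire, floor):
        key = clone.cdr3_aa.upper() if match_on == "cdr3" else (
            clone.cdr3_aa.upper(), clone.v_gene)
        if key in species_by_key:
            matched.append(clone)
            for sp in species_by_key[key]:
                by_species[sp] = by_species.get(sp, 0.0) + clone.count / total
    summed = float(sum(c.count for c in matched) / total)
    return SharedCloneScore(len(matched), summed, matched, by_species)


def cohort_annotation_report(
    cohort: Sequence[Repertoire],
    annotation_sets: Mapping[str, Sequence[AnnotationRecord]],
    match_on: str = "cdr3",
    floor: float = 0.0001,
    contrast_groups: tuple[str, str] = ("GVHD", "NO_GVHD"),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-(sample, annotation set) scores plus a rank-sum group comparison of
    the summed shared frequency per set."""
    rows = []
    for rep in cohort:
        for name, records in annotation_sets.items():
            score = shared_clone_score(rep, records, match_on=match_on, floor=floor)
            rows.append(
                (rep.sample_id, rep.group or "", name, score.n_shared,
                 score.summed_frequency)
            )
    report = pd.DataFrame(
        rows,
        columns=["sample_id", "group", "annotation_set", "n_shared",
                 "summed_frequency"],
    )
    tests = []
    ga, gb = contrast_groups
    for name in annotation_sets:
        sub = report[report["annotation_set"] == name]
        va = sub.loc[sub["group"] == ga, "summed_frequency"].to_numpy()
        vb = sub.loc[sub["group"] == gb, "summed_frequency"].to_numpy()
        if len(va) < 2 or len(vb) < 2:
            continue
        res = compare_groups({ga: va, gb: vb}, test="wilcoxon_rank_sum")
        tests.append(
            (name, f"{ga}_vs_{gb}", float(np.median(va)), float(np.median(vb)),
             res.statistic, res.p)
        )
    test_frame = pd.DataFrame(
        tests,
        columns=["annotation_set", "contrast", f"median_a", "median_b",
                 "statistic", "p"],
    )
    return report, test_frame
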