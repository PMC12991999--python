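"""Reading and writing clonotype and annotation tables.

Supported dialects, all UTF-8 tab-separated with a mandatory header row:

* **AIRR Rearrangement TSV** (MiAIRR column names): ``junction_aa``,
  ``v_call``, ``j_call``, ``productive`` and a count column
  (``duplicate_count`` preferred, ``consensus_count`` as fallback).
* **Simple clonotype TSV**: five columns ``cdr3_aa, v_gene, j_gene, count,
  chain``; all rows assumed productive.
* **VDJdb export TSV** (``cdr3``, ``antigen.species`` and optionally
  ``v.segm`` / ``j.segm``) and a simple two-column annotation dialect
  (``cdr3_aa``, ``antigen_species``).

Ingestion enforces the filters every downstream stage assumes: productive
rows only, CDR3s restricted to the 20 amino-acid alphabet, allele suffixes
stripped from gene calls, and duplicate identity keys merged by summing
counts.  Rows failing validation are dropped and counted in the log.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .repertoire import (
    AnnotationRecord,
    ConfigError,
    EmptyRepertoireError,
    KEY_COLUMNS,
    Repertoire,
    RepertoireFormatError,
    is_valid_cdr3,
    normalize_gene,
)

logger = logging.getLogger(__name__)

_TRUTHY = {"t", "true", "1", "yes", "y"}
_FALSY = {"f", "false", "0", "no", "n", ""}

SIMPLE_COLUMNS = ["cdr3_aa", "v_gene", "j_gene", "count", "chain"]
MANIFEST_COLUMNS = ["sample_id", "subject_id", "group", "stage", "path"]


def _as_bool(value: object) -> bool:
    s = str(value).strip().lower()
    if s in _TRUTHY:
        return True
    if s in _FALSY or s == "nan":
        return False
    raise RepertoireFormatError(f"unrecognized productive flag {value!r}")


def _read_tsv(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)


def _finalize(
    df: pd.DataFrame,
    sample_id: str,
    chain_filter: Optional[str],
    dropped: int,
    path,
    **meta,
) -> Repertoire:
    """Shared tail of both clonotype readers: chain handling + assembly."""
    df = df.copy()
    df["chain"] = df["v_gene"].str[:3].where(df["v_gene"].str.len() >= 3, df["chain"])
    if chain_filter is not None:
        df = df[df["chain"] == chain_filter]
        chain = chain_filter
    else:
        chains = sorted(set(df["chain"]))
        if len(chains) > 1:
            raise RepertoireFormatError(
                f"{path}: mixed chains {chains}; pass an explicit chain filter"
            )
        chain = chains[0] if chains else "TRB"
    if len(df) == 0 or df["count"].sum() == 0:
        raise EmptyRepertoireError(f"{path}: no productive clonotypes after filtering")
    if dropped:
        logger.info("%s: dropped %d rows failing validation", path, dropped)
    rep = Repertoire(
        sample_id=sample_id,
        clonotypes=df[KEY_COLUMNS + ["count"]].reset_index(drop=True),
        chain=chain,
        **meta,
    )
    return rep


def read_airr_table(
    path,
    chain_filter: Optional[str] = None,
    sample_id: Optional[str] = None,
    **meta,
) -> Repertoire:
    """Read an AIRR Rearrangement TSV into a :class:`Repertoire`.

    Keeps only productive rows whose ``junction_aa`` passes the amino-acid
    alphabet check; merges duplicate (CDR3, V, J) keys by summing counts.
    ``duplicate_count`` is preferred over ``consensus_count``.
    """
    raw = _read_tsv(path)
    for col in ("junction_aa", "v_call", "j_call", "productive"):
        if col not in raw.columns:
            raise RepertoireFormatError(f"{path}: missing mandatory column {col!r}")
    if "duplicate_count" in raw.columns:
        count_col = "duplicate_count"
    elif "consensus_count" in raw.columns:
        count_col = "consensus_count"
    else:
        raise RepertoireFormatError(
            f"{path}: missing mandatory column 'duplicate_count' (or 'consensus_count')"
        )
    logger.debug("%s: using count column %s", path, count_col)

    productive = raw["productive"].map(_as_bool)
    valid_cdr3 = raw["junction_aa"].map(is_valid_cdr3)
    keep = productive & valid_cdr3
    dropped = int(productive.sum() - keep.sum())  # productive rows failing checks

    df = pd.DataFrame(
        {
            "cdr3_aa": raw.loc[keep, "junction_aa"],
            "v_gene": raw.loc[keep, "v_call"].map(normalize_gene),
            "j_gene": raw.loc[keep, "j_call"].map(normalize_gene),
            "chain": "",
        }
    )
    try:
        df["count"] = pd.to_numeric(raw.loc[keep, count_col], errors="raise").astype(
            np.int64
        )
    except (ValueError, TypeError) as exc:
        raise RepertoireFormatError(f"{path}: non-integer {count_col}: {exc}") from exc
    if sample_id is None:
        sample_id = Path(path).stem
    return _finalize(df, sample_id, chain_filter, dropped, path, **meta)


def read_simple_table(path, sample_id: Optional[str] = None, **meta) -> Repertoire:
    """Read the documented 5-column clonotype dialect (productive assumed)."""
    raw = _read_tsv(path)
    missing = [c for c in SIMPLE_COLUMNS if c not in raw.columns]
    if missing:
        raise RepertoireFormatError(f"{path}: missing mandatory column(s) {missing}")
    counts = pd.to_numeric(raw["count"], errors="coerce")
    bad = counts.isna() | (counts != counts.round()) | (counts < 0)
    if bad.any():
        line = int(bad.idxmax()) + 2  # +1 header, +1 one-based
        raise RepertoireFormatError(
            f"{path}: invalid count {raw['count'][bad.idxmax()]!r} at line {line}"
        )
    valid = raw["cdr3_aa"].map(is_valid_cdr3)
    dropped = int((~valid).sum())
    df = pd.DataFrame(
        {
            "cdr3_aa": raw.loc[valid, "cdr3_aa"],
            "v_gene": raw.loc[valid, "v_gene"].map(normalize_gene),
            "j_gene": raw.loc[valid, "j_gene"].map(normalize_gene),
            "count": counts[valid].astype(np.int64),
            "chain": raw.loc[valid, "chain"],
        }
    )
    if sample_id is None:
        sample_id = Path(path).stem
    return _finalize(df, sample_id, None, dropped, path, **meta)


def write_repertoire(repertoire: Repertoire, path) -> None:
    """Write a repertoire in the simple 5-column dialect (round-trips with
    :func:`read_simple_table` up to clonotype order)."""
    if repertoire.total_reads <= 0:
        raise EmptyRepertoireError(
            f"refusing to write empty repertoire {repertoire.sample_id}"
        )
    df = repertoire.clonotypes[KEY_COLUMNS + ["count"]].copy()
    df["chain"] = repertoire.chain
    df.to_csv(path, sep="\t", index=False, columns=SIMPLE_COLUMNS)


def read_annotation_table(path, dialect: str = "vdjdb") -> list[AnnotationRecord]:
    """Read an annotated-CDR3 table; records deduplicated on
    (cdr3, antigen species)."""
    if dialect == "vdjdb":
        colmap = {"cdr3": "cdr3_aa", "antigen.species": "antigen_species"}
        optmap = {"v.segm": "v_gene", "j.segm": "j_gene"}
    elif dialect == "simple":
        colmap = {"cdr3_aa": "cdr3_aa", "antigen_species": "antigen_species"}
        optmap = {"v_gene": "v_gene", "j_gene": "j_gene"}
    else:
        raise ConfigError(f"unknown annotation dialect {dialect!r}")
    raw = _read_tsv(path)
    missing = [c for c in colmap if c not in raw.columns]
    if missing:
        raise RepertoireFormatError(f"{path}: missing mandatory column(s) {missing}")
    if len(raw) == 0:
        logger.warning("%s: empty annotation table", path)
        return []
    records: list[AnnotationRecord] = []
    seen: set[tuple[str, str]] = set()
    source = Path(path).stem
    for _, row in raw.iterrows():
        cdr3 = str(row[next(iter(colmap))]).upper()
        species = str(row[list(colmap)[1]])
        if not is_valid_cdr3(cdr3):
            continue
        key = (cdr3, species)
        if key in seen:
            continue
        seen.add(key)
        genes = {
            tgt: normalize_gene(row[src]) or None
            for src, tgt in optmap.items()
            if src in raw.columns
        }
        records.append(
            AnnotationRecord(cdr3_aa=cdr3, antigen_species=species, source=source, **genes)
        )
    return records


def write_annotation_table(records: Sequence[AnnotationRecord], path) -> None:
    pd.DataFrame(
        {
            "cdr3_aa": [r.cdr3_aa for r in records],
            "antigen_species": [r.antigen_species for r in records],
            "v_gene": [r.v_gene or "" for r in records],
            "j_gene": [r.j_gene or "" for r in records],
        }
    ).to_csv(path, sep="\t", index=False)


# -- cohort manifests -------------------------------------------------------


def write_manifest(cohort: Sequence[Repertoire], paths: Sequence, out_path) -> None:
    """Write the manifest contract passed between pipeline stages."""
    pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in cohort],
            "subject_id": [r.subject_id for r in cohort],
            "group": [r.group or "" for r in cohort],
            "stage": ["" if r.stage is None else r.stage for r in cohort],
            "path": [str(p) for p in paths],
        }
    ).to_csv(out_path, sep="\t", index=False)


def read_manifest(path) -> list[Repertoire]:
    """Load every sample referenced by a manifest TSV (simple dialect files)."""
    man = _read_tsv(path)
    missing = [c for c in MANIFEST_COLUMNS if c not in man.columns]
    if missing:
        raise RepertoireFormatError(f"{path}: manifest missing column(s) {missing}")
    base = Path(path).parent
    cohort = []
    for row in man.itertuples():
        p = Path(row.path)
        if not p.is_absolute():
            p = base / p
        stage = None if row.stage == "" else int(float(row.stage))
        cohort.append(
            read_simple_table(
                p,
                sample_id=row.sample_id,
                subject_id=row.subject_id,
                group=row.group or None,
                stage=stage,
            )
        )
    return cohort
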