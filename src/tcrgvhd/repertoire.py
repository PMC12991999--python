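"""Core domain objects: clonotypes, repertoires and antigen annotations.

A *clonotype* is a unique receptor rearrangement — here defined at the amino
acid level as the (CDR3, V segment, J segment) triple — with an associated
read count.  A *repertoire* is one sample's collection of clonotypes plus
subject / clinical-group / stage metadata, and is the unit on which depth
normalization and every diversity statistic operate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, NamedTuple, Optional

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: the 20 standard amino-acid one-letter codes
AA_LETTERS = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: clinical group labels used throughout the pipeline
GROUPS = ("GVHD", "NO_GVHD", "HI", "GVHD_PRE")

CHAINS = ("TRA", "TRB")

#: columns that define clonotype identity
KEY_COLUMNS = ["cdr3_aa", "v_gene", "j_gene"]


class RepertoireFormatError(ValueError):
    """Malformed clonotype / annotation table."""


class EmptyRepertoireError(ValueError):
    """A repertoire with zero productive reads is not analyzable."""


class ConfigError(ValueError):
    """Invalid parameter or configuration value."""


def is_valid_cdr3(seq: object) -> bool:
    """True when *seq* is a non-empty uppercase string over the 20 amino acids."""
    if not isinstance(seq, str) or not seq:
        return False
    return all(c in AA_LETTERS for c in seq)


def normalize_gene(name: object) -> str:
    """Strip the allele suffix from a gene call: ``TRBV15*01`` -> ``TRBV15``.

    Segment-level names are what usage tallies and cross-sample comparisons
    operate on; allele-level resolution is upstream aligner detail.
    """
    if name is None or (isinstance(name, float) and np.isnan(name)):
        return ""
    return str(name).split("*")[0].strip()


class Clonotype(NamedTuple):
    """One unique receptor sequence with gene calls and a read count."""

    cdr3_aa: str
    v_gene: str
    j_gene: str
    count: int
    chain: str = "TRB"
    productive: bool = True
    cdr3_nt: Optional[str] = None


@dataclass
class Repertoire:
    """One sample's clonotype table plus metadata.

    ``clonotypes`` is a DataFrame with columns ``cdr3_aa, v_gene, j_gene,
    count`` (and optionally ``cdr3_nt``), unique on the identity key; duplicate
    keys are merged by summing counts at construction time.  Frequencies are
    never stored — they are always derived as ``count / total_reads``.
    """

    sample_id: str
    clonotypes: pd.DataFrame
    chain: str = "TRB"
    subject_id: str = ""
    group: Optional[str] = None
    stage: Optional[int] = None
    donor_age: Optional[int] = None

    def __post_init__(self) -> None:
        df = self.clonotypes
        missing = [c for c in KEY_COLUMNS + ["count"] if c not in df.columns]
        if missing:
            raise RepertoireFormatError(f"clonotype table missing columns: {missing}")
        if self.chain not in CHAINS:
            raise ConfigError(f"unknown chain {self.chain!r}; expected one of {CHAINS}")
        if self.group is not None and self.group not in GROUPS:
            raise ConfigError(f"unknown group {self.group!r}; expected one of {GROUPS}")
        df = df.copy()
        df["count"] = df["count"].astype(np.int64)
        if (df["count"] < 0).any():
            raise RepertoireFormatError("negative clonotype counts")
        if df.duplicated(KEY_COLUMNS).any():
            agg = {"count": "sum"}
            if "cdr3_nt" in df.columns:
                agg["cdr3_nt"] = "first"
            df = df.groupby(KEY_COLUMNS, as_index=False, sort=False).agg(agg)
        df = df.reset_index(drop=True)
        object.__setattr__(self, "clonotypes", df)

    # -- derived quantities -------------------------------------------------

    @property
    def total_reads(self) -> int:
        return int(self.clonotypes["count"].sum())

    @property
    def richness(self) -> int:
        return int((self.clonotypes["count"] >= 1).sum())

    def counts(self) -> np.ndarray:
        return self.clonotypes["count"].to_numpy()

    def frequencies(self) -> np.ndarray:
        total = self.total_reads
        if total <= 0:
            raise EmptyRepertoireError(f"repertoire {self.sample_id} has no reads")
        return self.counts() / total

    def keys(self) -> list[tuple[str, str, str]]:
        return list(
            zip(
                self.clonotypes["cdr3_aa"],
                self.clonotypes["v_gene"],
                self.clonotypes["j_gene"],
            )
        )

    def to_clonotypes(self) -> list[Clonotype]:
        return [
            Clonotype(r.cdr3_aa, r.v_gene, r.j_gene, int(r.count), self.chain)
            for r in self.clonotypes.itertuples()
        ]

    def with_counts(self, counts: np.ndarray, drop_zero: bool = True) -> "Repertoire":
        """Copy of this repertoire with replaced counts (zero rows dropped)."""
        df = self.clonotypes.copy()
        df["count"] = np.asarray(counts, dtype=np.int64)
        if drop_zero:
            df = df[df["count"] > 0].reset_index(drop=True)
        return replace(self, clonotypes=df)

    # -- constructors -------------------------------------------------------

    @classmethod
    def from_counts(
        cls,
        counts: Mapping[str, int],
        sample_id: str = "sample",
        v_gene: str = "TRBV1",
        j_gene: str = "TRBJ1-1",
        **meta,
    ) -> "Repertoire":
        """Build a single-V/J repertoire from a ``{cdr3: count}`` mapping (tests,
        examples)."""
        df = pd.DataFrame(
            {
                "cdr3_aa": list(counts),
                "v_gene": v_gene,
                "j_gene": j_gene,
                "count": list(counts.values()),
            }
        )
        return cls(sample_id=sample_id, clonotypes=df, **meta)

    @classmethod
    def from_clonotypes(
        cls, clonotypes: Iterable[Clonotype], sample_id: str = "sample", **meta
    ) -> "Repertoire":
        rows = list(clonotypes)
        df = pd.DataFrame(
            {
                "cdr3_aa": [c.cdr3_aa for c in rows],
                "v_gene": [c.v_gene for c in rows],
                "j_gene": [c.j_gene for c in rows],
                "count": [c.count for c in rows],
            }
        )
        chain = rows[0].chain if rows else "TRB"
        meta.setdefault("chain", chain)
        return cls(sample_id=sample_id, clonotypes=df, **meta)


@dataclass(frozen=True)
class AnnotationRecord:
    """One annotated CDR3: antigen species (e.g. CMV, EBV) or tissue label."""

    cdr3_aa: str
    antigen_species: str
    source: str = ""
    v_gene: Optional[str] = None
    j_gene: Optional[str] = None


def equal_repertoires(a: Repertoire, b: Repertoire) -> bool:
    """Equality up to clonotype order (identity keys and counts)."""
    if a.sample_id != b.sample_id or a.chain != b.chain:
        return False
    key = KEY_COLUMNS
    da = a.clonotypes.sort_values(key).reset_index(drop=True)
    db = b.clonotypes.sort_values(key).reset_index(drop=True)
    cols = key + ["count"]
    return da[cols].equals(db[cols])
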