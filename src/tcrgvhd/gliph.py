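"""GLIPH-style specificity-group clustering of CDR3 sequences.

Two complementary notions of shared specificity are implemented, following
the local/global decomposition of the GLIPH family of algorithms:

* **local groups** — interior k-mer motifs (k in 2..4 by default, terminal
  residues trimmed) that are significantly enriched in the pooled patient
  CDR3s relative to a naive reference repertoire.  For each candidate motif
  the null distribution of its support in a random reference subset of the
  same size as the sample pool is simulated (``simulation_depth`` draws);
  the support of a fixed motif in a uniform size-n subset of N reference
  CDR3s carrying it K times is exactly hypergeometric, so the subsets are
  simulated as hypergeometric variates.  A motif is retained when its
  fold enrichment over the simulated mean and its add-one empirical p-value
  both pass their thresholds.
* **global groups** — connected components of the graph linking equal-length
  CDR3s whose trimmed interiors differ at no more than one position.

Input clonotypes are pre-filtered per sample to those above a frequency
floor (default 0.01% of reads, strict) and a CDR3 length cutoff (default 8),
then pooled across all samples.
"""

from __future__ import annotations

import hashlib
import logging
import zlib
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .repertoire import ConfigError, Repertoire

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GliphConfig:
    simulation_depth: int = 1000
    kmer_min_depth: int = 3
    cdr3_length_cutoff: int = 8
    kmer_lengths: tuple[int, ...] = (2, 3, 4)
    min_fold_enrichment: float = 10.0
    p_threshold: float = 0.05
    interior_trim: tuple[int, int] = (3, 3)
    frequency_floor: float = 0.0001  # 0.01% of reads, strict
    seed: int = 0

    def __post_init__(self) -> None:
        if self.simulation_depth < 1:
            raise ConfigError("simulation_depth must be >= 1")
        left, right = self.interior_trim
        # the shortest admissible CDR3 must retain a non-empty interior;
        # k-mers longer than a given interior simply do not occur in it
        if self.cdr3_length_cutoff < left + right + 1:
            raise ConfigError(
                "cdr3_length_cutoff must leave a non-empty interior after trimming"
            )


@dataclass(frozen=True)
class MotifGroup:
    """A putative shared-specificity group.

    ``members`` are (sample_id, cdr3_aa, v_gene) triples drawn from the
    filtered pool.  Local groups carry the enrichment fold and empirical
    p-value of their motif; global groups are near-identity clusters.
    """

    group_id: str
    kind: str  # "local" | "global"
    signature: str
    members: frozenset
    enrichment_fold: Optional[float] = None
    p_empirical: Optional[float] = None

    @property
    def sample_ids(self) -> frozenset:
        return frozenset(m[0] for m in self.members)


def group_id_for(kind: str, signature: str) -> str:
    digest = hashlib.sha1(f"{kind}:{signature}".encode()).hexdigest()[:12]
    return f"{kind[0]}_{digest}"


def interior(cdr3_aa: str, trim: tuple[int, int] = (3, 3)) -> str:
    """Interior of a CDR3 after dropping the germline-dominated termini."""
    left, right = trim
    if len(cdr3_aa) < left + right + 1:
        raise ConfigError(
            f"CDR3 {cdr3_aa!r} too short for trim {trim}; pre-filter by length"
        )
    return cdr3_aa[left: len(cdr3_aa) - right]


def select_input_clonotypes(
    cohort: Sequence[Repertoire], config: GliphConfig
) -> pd.DataFrame:
    """Pool per-sample clonotypes above the frequency floor (strict) and at or
    above the length cutoff, across all samples simultaneously.

    Returns a DataFrame with columns ``sample_id, cdr3_aa, v_gene``.
    """
    frames = []
    for rep in cohort:
        df = rep.clonotypes
        freq = df["count"] / rep.total_reads
        keep = (freq > config.frequency_floor) & (
            df["cdr3_aa"].str.len() >= config.cdr3_length_cutoff
        )
        sub = df.loc[keep, ["cdr3_aa", "v_gene"]].copy()
        sub.insert(0, "sample_id", rep.sample_id)
        frames.append(sub)
    pool = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
    if len(pool) == 0:
        raise ConfigError("no clonotypes pass the frequency/length filters")
    return pool.drop_duplicates().reset_index(drop=True)


def kmer_table(
    cdr3s: Iterable[str], k: int, trim: tuple[int, int] = (3, 3)
) -> dict[str, tuple[int, set]]:
    """Map each interior k-mer to (support, supporting CDR3 set).

    Support uses presence semantics: each distinct CDR3 contributes each of
    its interior k-mers once, regardless of multiplicity.
    """
    table: dict[str, set] = {}
    for cdr3 in set(cdr3s):
        inner = interior(cdr3, trim)
        for i in range(len(inner) - k + 1):
            table.setdefault(inner[i: i + k], set()).add(cdr3)
    return {m: (len(s), s) for m, s in table.items()}


def _kmer_counts(cdr3s: Iterable[str], k: int, trim: tuple[int, int]) -> dict[str, int]:
    """Presence-count variant of :func:`kmer_table` (no supporter sets); used
    for the reference pool where only K is needed."""
    counts: dict[str, int] = {}
    for cdr3 in set(cdr3s):
        inner = interior(cdr3, trim)
        seen = {inner[i: i + k] for i in range(len(inner) - k + 1)}
        for m in seen:
            counts[m] = counts.get(m, 0) + 1
    return counts


def _reference_cdr3s(reference, config: GliphConfig) -> list[str]:
    if isinstance(reference, Repertoire):
        seqs = reference.clonotypes["cdr3_aa"]
    elif isinstance(reference, pd.DataFrame):
        seqs = reference["cdr3_aa"]
    else:
        seqs = pd.Series(list(reference))
    seqs = seqs[seqs.str.len() >= config.cdr3_length_cutoff]
    return sorted(set(seqs))


def _tested_motifs(sample_cdr3s, ref_cdr3s, config: GliphConfig):
    """Yield (motif, k, obs, supporters, K, fold, p) for every motif passing
    the minimum-support cutoff.  The null support of a motif in a uniform
    random reference subset of the sample-pool size is hypergeometric (see
    module docstring); each motif draws its simulated subsets from an RNG
    stream keyed on (seed, k, motif) so results are order-invariant."""
    n, N = len(sample_cdr3s), len(ref_cdr3s)
    depth = config.simulation_depth
    for k in sorted(config.kmer_lengths):
        sample_kmers = kmer_table(sample_cdr3s, k, config.interior_trim)
        ref_counts = _kmer_counts(ref_cdr3s, k, config.interior_trim)
        for motif in sorted(sample_kmers):
            obs, supporters = sample_kmers[motif]
            if obs < config.kmer_min_depth:
                continue
            K = ref_counts.get(motif, 0)
            rng = np.random.default_rng(
                np.random.SeedSequence(
                    [config.seed % 2**31, k, zlib.crc32(motif.encode())]
                )
            )
            if K > 0:
                sims = rng.hypergeometric(K, N - K, n, size=depth)
            else:
                sims = np.zeros(depth)
            p = (1.0 + float((sims >= obs).sum())) / (depth + 1.0)
            fold = obs / max(float(sims.mean()), 1.0 / depth)
            yield motif, k, obs, supporters, K, fold, p


def local_motif_enrichment(
    sample_pool: pd.DataFrame,
    reference,
    config: GliphConfig,
) -> list[MotifGroup]:
    """Motif groups from k-mer enrichment of the pooled sample CDR3s against
    a reference repertoire (see module docstring for the null model)."""
    sample_cdr3s = sorted(set(sample_pool["cdr3_aa"]))
    ref_cdr3s = _reference_cdr3s(reference, config)
    n, N = len(sample_cdr3s), len(ref_cdr3s)
    if N < n:
        raise ConfigError(
            f"reference ({N} CDR3s) smaller than sample pool ({n}); cannot subsample"
        )
    if N < 10 * n:
        logger.warning("reference only %.1fx the sample pool; >=10x recommended", N / n)

    # pool rows indexed by CDR3 for member lookup
    rows_by_cdr3: dict[str, list[tuple]] = {}
    for row in sample_pool.itertuples(index=False):
        rows_by_cdr3.setdefault(row.cdr3_aa, []).append(tuple(row))

    groups: list[MotifGroup] = []
    for motif, k, obs, supporters, K, fold, p in _tested_motifs(
        sample_cdr3s, ref_cdr3s, config
    ):
        if fold >= config.min_fold_enrichment and p <= config.p_threshold:
            members = frozenset(
                t for c in supporters for t in rows_by_cdr3.get(c, ())
            )
            groups.append(
                MotifGroup(
                    group_id=group_id_for("local", motif),
                    kind="local",
                    signature=motif,
                    members=members,
                    enrichment_fold=float(fold),
                    p_empirical=float(p),
                )
            )
    return groups


def motif_pvalues(
    sample_pool: pd.DataFrame, reference, config: GliphConfig
) -> pd.DataFrame:
    """Empirical p-value and fold for every tested motif (support >= min
    depth), without applying the retention thresholds.  Used for null
    calibration checks."""
    sample_cdr3s = sorted(set(sample_pool["cdr3_aa"]))
    ref_cdr3s = _reference_cdr3s(reference, config)
    if len(ref_cdr3s) < len(sample_cdr3s):
        raise ConfigError("reference smaller than sample pool")
    rows = [
        (motif, k, obs, K, fold, p)
        for motif, k, obs, _, K, fold, p in _tested_motifs(
            sample_cdr3s, ref_cdr3s, config
        )
    ]
    return pd.DataFrame(
        rows, columns=["motif", "k", "support", "ref_support", "fold", "p"]
    )


class _UnionFind:
    def __init__(self, items: Sequence[str]):
        self.parent = {x: x for x in items}

    def find(self, x: str) -> str:
        root = x
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[x] != root:
            self.parent[x], x = root, self.parent[x]
        return root

    def union(self, a: str, b: str) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def global_similarity_groups(
    clonotype_pool: pd.DataFrame, config: GliphConfig
) -> list[MotifGroup]:
    """Near-identity clusters: equal-length CDR3s whose interiors differ at
    no more than one position, connected-component closure, components of
    two or more CDR3s."""
    cdr3s = sorted(set(clonotype_pool["cdr3_aa"]))
    uf = _UnionFind(cdr3s)
    buckets: dict[tuple, str] = {}
    for cdr3 in cdr3s:
        inner = interior(cdr3, config.interior_trim)
        L = len(cdr3)
        for i in range(len(inner)):
            key = (L, i, inner[:i] + "\x00" + inner[i + 1:])
            first = buckets.setdefault(key, cdr3)
            if first != cdr3:
                uf.union(first, cdr3)

    components: dict[str, list[str]] = {}
    for cdr3 in cdr3s:
        components.setdefault(uf.find(cdr3), []).append(cdr3)

    rows_by_cdr3: dict[str, list[tuple]] = {}
    for row in clonotype_pool.itertuples(index=False):
        rows_by_cdr3.setdefault(row.cdr3_aa, []).append(tuple(row))

    groups = []
    for comp in components.values():
        if len(comp) < 2:
            continue
        signature = min(comp)
        members = frozenset(t for c in comp for t in rows_by_cdr3.get(c, ()))
        groups.append(
            MotifGroup(
                group_id=group_id_for("global", signature),
                kind="global",
                signature=signature,
                members=members,
            )
        )
    return sorted(groups, key=lambda g: g.signature)


def build_gliph_groups(
    cohort: Sequence[Repertoire],
    reference,
    config: Optional[GliphConfig] = None,
) -> list[MotifGroup]:
    """Full clustering: filter and pool the cohort, then take the union of
    local (motif-enrichment) and global (near-identity) groups."""
    config = config or GliphConfig()
    pool = select_input_clonotypes(cohort, config)
    local = local_motif_enrichment(pool, reference, config)
    global_ = global_similarity_groups(pool, config)
    return sorted(local + global_, key=lambda g: (g.kind, g.signature))


def groups_to_frames(groups: Sequence[MotifGroup]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(groups table, membership table) for writing as TSV."""
    gtab = pd.DataFrame(
        {
            "group_id": [g.group_id for g in groups],
            "kind": [g.kind for g in groups],
            "signature": [g.signature for g in groups],
            "enrichment_fold": [g.enrichment_fold for g in groups],
            "p_empirical": [g.p_empirical for g in groups],
            "n_members": [len(g.members) for g in groups],
            "n_samples": [len(g.sample_ids) for g in groups],
        }
    )
    rows = [
        (g.group_id, s, c, v)
        for g in groups
        for (s, c, v) in sorted(g.members)
    ]
    mtab = pd.DataFrame(rows, columns=["group_id", "sample_id", "cdr3_aa", "v_gene"])
    return gtab, mtab
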