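"""Chromatin-state annotation of probes and the variance-matched resampling
enrichment test.

Raw segmentation labels (e.g. a 25-state ChromHMM track) are collapsed to a
small set of functional categories via a user-supplied two-column map, probes
are assigned the category covering their position, and enrichment of a target
probe set is assessed against repeated random draws matched on per-probe
methylation variance.
"""

from __future__ import annotations

import bisect
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

UNANNOTATED = "unannotated"


@dataclass
class EnrichmentResult:
    category: str
    observed: float
    null_mean: float
    fold: float
    se_fold: float
    z: float
    p_norm: float
    flagged: bool = False


class StateAnnotation:
    """Interval index over collapsed chromatin-state categories.

    Intervals are stored half-open 0-based per chromosome; point queries use
    1-based positions (the probe convention).  Overlapping input intervals
    that collapse to the same category are merged; should differently
    labelled intervals overlap, the one starting last at the query point
    wins (deterministic).
    """

    def __init__(self, intervals: list[tuple[str, int, int, str]], categories: set[str]):
        self.categories = set(categories)
        self._by_chrom: dict[str, tuple[list[int], list[int], list[str]]] = {}
        by_chrom: dict[str, list[tuple[int, int, str]]] = {}
        for chrom, start, end, cat in intervals:
            by_chrom.setdefault(chrom, []).append((start, end, cat))
        for chrom, ivs in by_chrom.items():
            ivs.sort()
            merged: list[list] = []
            for s, e, c in ivs:
                if merged and merged[-1][2] == c and s <= merged[-1][1]:
                    merged[-1][1] = max(merged[-1][1], e)
                else:
                    merged.append([s, e, c])
            self._by_chrom[chrom] = (
                [m[0] for m in merged],
                [m[1] for m in merged],
                [m[2] for m in merged],
            )
        self._max_span = {
            chrom: max(e - s for s, e in zip(v[0], v[1]))
            for chrom, v in self._by_chrom.items()
        }

    def query(self, chrom: str, pos_1based: int) -> str:
        """Category covering a 1-based position; ``unannotated`` in gaps."""
        entry = self._by_chrom.get(chrom)
        if entry is None:
            return UNANNOTATED
        starts, ends, cats = entry
        p = pos_1based - 1
        span = self._max_span[chrom]
        i = bisect.bisect_right(starts, p) - 1
        while i >= 0:
            if p < ends[i]:
                return cats[i]
            if starts[i] < p - span:
                break
            i -= 1
        return UNANNOTATED


def read_collapse_map(path) -> dict[str, str]:
    """Two-column tab-delimited raw-state -> category mapping (no header)."""
    cmap: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if len(parts) >= 2:
                cmap[parts[0]] = parts[1]
    if not cmap:
        raise ValueError(f"{path}: empty collapse map")
    return cmap


def read_bed_states(path, collapse_map: dict[str, str]) -> StateAnnotation:
    """Read a BED (0-based half-open, state label in column 4) and collapse labels.

    An interval whose label has no map entry is an error naming the label.
    """
    intervals = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if not parts or parts[0].startswith(("track", "browser", "#")):
                continue
            if len(parts) < 4:
                raise ValueError(f"{path}:{ln}: BED line needs 4 columns (chrom start end state)")
            chrom, start, end, label = parts[0], int(parts[1]), int(parts[2]), parts[3]
            if label not in collapse_map:
                raise KeyError(f"{path}:{ln}: state label {label!r} missing from the collapse map")
            intervals.append((chrom, start, end, collapse_map[label]))
    return StateAnnotation(intervals, categories=set(collapse_map.values()))


def assign_category(probes, ann) -> dict[str, str]:
    """Map each probe to the category covering its position.

    ``probes`` is an iterable of objects with ``probe_id``/``chrom``/``bp``.
    ``ann`` is one :class:`StateAnnotation` or a list of tracks, in which
    case the per-probe majority category across tracks is used (ties broken
    lexicographically).
    """
    tracks = ann if isinstance(ann, (list, tuple)) else [ann]
    out: dict[str, str] = {}
    for p in probes:
        votes: dict[str, int] = {}
        for tr in tracks:
            c = tr.query(p.chrom, p.bp)
            votes[c] = votes.get(c, 0) + 1
        best = sorted(votes.items(), key=lambda kv: (-kv[1], kv[0]))[0][0]
        out[p.probe_id] = best
    n_un = sum(1 for c in out.values() if c == UNANNOTATED)
    if n_un:
        logger.info("assign_category: %d of %d probe(s) unannotated", n_un, len(out))
    return out


def variance_matched_sample(
    universe: pd.DataFrame,
    targets,
    n_bins: int = 100,
    rng=None,
) -> list[str]:
    """Draw one matched probe per target from equal-frequency variance bins.

    ``universe`` needs columns ``probe_id`` and ``variance``; every target
    id must be present.  Each draw comes uniformly from the target's bin
    excluding the target itself; a bin holding only its target falls back to
    the nearest nonempty bin (with replacement, logged).
    """
    rng = np.random.default_rng(rng)
    uni = universe.reset_index(drop=True)
    ids = uni["probe_id"].to_numpy()
    id_pos = {pid: i for i, pid in enumerate(ids)}
    targets = list(targets)
    missing = [t for t in targets if t not in id_pos]
    if missing:
        raise ValueError(f"target probe(s) not in universe: {missing[:5]!r}")
    var = uni["variance"].to_numpy(float)
    if not np.all(np.isfinite(var)) or np.any(var < 0):
        raise ValueError("variances must be finite and nonnegative")
    n_bins = min(n_bins, len(uni))
    bins = pd.qcut(pd.Series(var).rank(method="first"), q=n_bins, labels=False).to_numpy()
    members: dict[int, np.ndarray] = {b: np.flatnonzero(bins == b) for b in range(n_bins)}

    sampled: list[str] = []
    fallbacks = 0
    for t in targets:
        i = id_pos[t]
        b = int(bins[i])
        pool = members[b][members[b] != i]
        if pool.size == 0:
            fallbacks += 1
            for off in range(1, n_bins):  # nearest nonempty bin
                for bb in (b - off, b + off):
                    if 0 <= bb < n_bins and members[bb].size:
                        pool = members[bb]
                        break
                if pool.size:
                    break
        sampled.append(ids[rng.choice(pool)])
    if fallbacks:
        logger.info("variance_matched_sample: %d target(s) used nearest-bin fallback", fallbacks)
    return sampled


def enrichment_test(
    targets,
    universe: pd.DataFrame,
    ann=None,
    n_fold_reps: int = 500,
    n_se_reps: int = 100,
    rng_seed=None,
    n_bins: int = 100,
) -> list[EnrichmentResult]:
    """Variance-matched enrichment of ``targets`` across categories.

    ``universe`` needs columns ``probe_id``, ``variance`` and ``category``
    (precompute the latter with :func:`assign_category`; ``ann`` is accepted
    for that purpose when a ``category`` column is absent and the universe
    carries ``chrom``/``bp``).  Fold = observed proportion / mean proportion
    over ``n_fold_reps`` matched null samples; its SE is the standard
    deviation of the per-replicate fold over the first ``n_se_reps``
    replicates.  A normal-approximation z = (fold - 1)/SE and its two-sided
    p are reported as a convenience.
    """
    if n_fold_reps < 2 or n_se_reps < 2:
        raise ValueError("replicate counts must be >= 2")
    uni = universe.reset_index(drop=True)
    if "category" not in uni.columns:
        if ann is None:
            raise ValueError("universe lacks a 'category' column and no annotation was given")
        probes = list(uni.itertuples(index=False))
        cat = assign_category(probes, ann)
        uni = uni.assign(category=[cat[p] for p in uni["probe_id"]])
    cat_of = dict(zip(uni["probe_id"], uni["category"]))
    categories = sorted(set(uni["category"]))
    targets = list(targets)
    if not targets:
        raise ValueError("empty target set")

    def proportions(ids) -> dict[str, float]:
        counts = {c: 0 for c in categories}
        for pid in ids:
            counts[cat_of[pid]] += 1
        n = len(ids)
        return {c: counts[c] / n for c in categories}

    observed = proportions(targets)
    rng = np.random.default_rng(rng_seed)
    reps = max(n_fold_reps, n_se_reps)
    null_props = {c: np.empty(reps) for c in categories}
    for r in range(reps):
        samp = variance_matched_sample(uni, targets, n_bins=n_bins, rng=rng)
        pr = proportions(samp)
        for c in categories:
            null_props[c][r] = pr[c]

    results = []
    for c in categories:
        nm = float(null_props[c][:n_fold_reps].mean())
        flagged = nm == 0.0
        fold = observed[c] / nm if nm > 0 else math.nan
        se_block = null_props[c][:n_se_reps]
        valid = se_block > 0
        if valid.sum() >= 2 and nm > 0:
            per_rep_fold = observed[c] / se_block[valid]
            se_fold = float(np.std(per_rep_fold, ddof=1))
            if valid.sum() < n_se_reps:
                flagged = True
        else:
            se_fold = math.nan
            flagged = True
        if se_fold and se_fold > 0 and math.isfinite(se_fold):
            z = (fold - 1.0) / se_fold
            p = float(min(2.0 * stats.norm.sf(abs(z)), 1.0))
        else:
            z, p = math.nan, math.nan
        results.append(EnrichmentResult(c, observed[c], nm, fold, se_fold, z, p, flagged))
    return results


def enrichment_table(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "category": r.category,
                "observed": r.observed,
                "null_mean": r.null_mean,
                "fold": r.fold,
                "se_fold": r.se_fold,
                "z": r.z,
                "p_norm": r.p_norm,
                "flagged": r.flagged,
            }
            for r in results
        ]
    )
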