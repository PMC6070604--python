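"""Actual-vs-estimated performance evaluation.

Two validation designs accompany the threshold method:

* **Known-truth curves** — on data with known clonal labels (simulated
  repertoires), the *actual* sensitivity and specificity of the
  distance-to-nearest classifier are computed per threshold from the
  labels and compared, via squared Pearson correlation over a threshold
  grid, with the *estimated* values read off the fitted mixture.
* **Spike-in specificity** — clones cannot span individuals, so single
  sequences drawn from foreign individuals and spiked into a base
  repertoire must come out as singleton clones; any merge is a false
  positive. Actual specificity is the fraction of spikes remaining
  singletons at each threshold, again compared with the mixture estimate.

"Actual" performance uses per-sequence membership-in-a-multi-sequence-
clone semantics: a sequence is condition-positive when its true clone has
at least two members, and predicted-positive when its distance-to-nearest
is below the threshold — the same event the mixture areas estimate.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .distance import (
    DistanceToNearest,
    distance_to_nearest_of,
    duplicate_index_sets,
    pairwise_mismatches,
    partition_by_vjl,
)
from .errors import ConsistencyError
from .io import Dataset, SequenceRecord
from .mixture import MixtureModel, fit_mixture
from .threshold import estimated_curves

__all__ = [
    "PerformanceCurve",
    "SpikeInDesign",
    "actual_performance",
    "performance_curve",
    "spike_in_specificity",
    "squared_pearson",
]

DEFAULT_GRID_POINTS = 50


def squared_pearson(a, b) -> float | None:
    """Squared Pearson correlation over pairs where both values are finite.

    Returns ``None`` (flagged, not an error) with fewer than 3 defined
    pairs or when either side has zero variance.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    mask = np.isfinite(a) & np.isfinite(b)
    if mask.sum() < 3:
        return None
    a, b = a[mask], b[mask]
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return None
    r = stats.pearsonr(a, b).statistic
    return float(r * r)


@dataclass
class PerformanceCurve:
    """Actual and estimated performance over a threshold grid.

    Undefined actual values (no condition positives/negatives at that
    point) are NaN; ``r2_*`` are ``None`` when the correlation itself is
    undefined.
    """

    grid: np.ndarray
    actual_sen: np.ndarray | None
    actual_spc: np.ndarray | None
    est_sen: np.ndarray | None
    est_spc: np.ndarray | None
    r2_sen: float | None
    r2_spc: float | None
    diagnostics: dict = field(default_factory=dict)


@dataclass
class SpikeInDesign:
    """Base repertoire plus one spiked-in sequence per foreign individual.

    ``spikes`` holds the first replicate's sample; ``foreign`` keeps the
    full foreign repertoires so each replicate can resample one sequence
    per individual (the paper's repeated-sampling design).
    """

    base: Dataset
    spikes: list[SequenceRecord]
    n_reps: int
    seed: int
    foreign: list[Dataset] = field(default_factory=list)


def actual_performance(
    dtn: DistanceToNearest, truth: dict[str, str], t: float
) -> tuple[float | None, float | None]:
    """Ground-truth (SEN, SPC) of the nearest-distance classifier at t.

    Condition positive: the sequence's true clone has >= 2 members.
    Predicted positive: its distance-to-nearest is < t. Sequences with
    undefined distance are excluded (and counted by the caller via
    ``dtn.n_defined``). A missing side returns ``None`` rather than
    raising.
    """
    clone_sizes = Counter(truth.values())
    tp = fn = fp = tn = 0
    for sid, d in dtn.values.items():
        if d is None:
            continue
        if sid not in truth:
            raise ConsistencyError(f"truth labels missing sequence {sid!r}")
        positive = clone_sizes[truth[sid]] >= 2
        predicted = d < t
        if positive and predicted:
            tp += 1
        elif positive:
            fn += 1
        elif predicted:
            fp += 1
        else:
            tn += 1
    sen = tp / (tp + fn) if tp + fn else None
    spc = tn / (tn + fp) if tn + fp else None
    return sen, spc


def performance_curve(
    dtn: DistanceToNearest,
    truth: dict[str, str],
    model: MixtureModel,
    grid: np.ndarray | None = None,
    n_grid: int = DEFAULT_GRID_POINTS,
) -> PerformanceCurve:
    """Actual and estimated SEN/SPC over a grid, with their R² agreement.

    The default grid is ``n_grid`` uniform points strictly inside the
    observed distance range (the same interval the threshold optimizer
    searches).
    """
    _, values = dtn.defined()
    if values.size == 0:
        raise ConsistencyError("no defined distance-to-nearest values")
    t1, t2 = float(values.min()), float(values.max())
    if grid is None:
        grid = np.linspace(t1, t2, n_grid + 2)[1:-1]
    grid = np.asarray(grid, dtype=float)
    est_sen, est_spc = estimated_curves(model, grid, t1, t2)
    actual = [actual_performance(dtn, truth, t) for t in grid]
    actual_sen = np.array([np.nan if s is None else s for s, _ in actual])
    actual_spc = np.array([np.nan if s is None else s for _, s in actual])
    r2_sen = squared_pearson(actual_sen, est_sen)
    r2_spc = squared_pearson(actual_spc, est_spc)
    return PerformanceCurve(
        grid=grid,
        actual_sen=actual_sen,
        actual_spc=actual_spc,
        est_sen=est_sen,
        est_spc=est_spc,
        r2_sen=r2_sen,
        r2_spc=r2_spc,
        diagnostics={
            "n_defined": dtn.n_defined,
            "n_undefined": len(dtn.values) - dtn.n_defined,
            "r2_flags": {
                "sen": "undefined" if r2_sen is None else "ok",
                "spc": "undefined" if r2_spc is None else "ok",
            },
        },
    )


def sample_spikes(
    foreign: list[Dataset], seed: int, rep: int
) -> list[SequenceRecord]:
    """Draw one sequence per foreign repertoire, renamed to a spike id.

    Deterministic in (seed, rep); spike ids ``spike<k>`` are disjoint from
    any simulated or experimental base id.
    """
    rng = np.random.default_rng([seed, rep])
    spikes = []
    for k, ds in enumerate(foreign):
        rec = ds.records[int(rng.integers(len(ds.records)))]
        spikes.append(
            SequenceRecord(f"spike{k}", rec.v_call, rec.j_call, rec.junction)
        )
    return spikes


def _spike_nearest_distances(
    merged: Dataset, spike_ids: set[str], v_level: str, j_level: str
) -> tuple[dict[str, float], float]:
    """Min distance from each spike to *any* other member of its group.

    Unlike distance-to-nearest, identical neighbors count (distance 0):
    under a single-linkage cut at t a spike stays a singleton clone iff
    this minimum is >= t, so these distances encode singleton status at
    every threshold at once. Spikes alone in their group are unchallenged
    (distance +inf); their fraction is returned alongside.
    """
    junctions = merged.junctions()
    groups = partition_by_vjl(merged, v_level, j_level)
    out: dict[str, float] = {}
    unchallenged = 0
    for group in groups:
        members = list(group.member_ids)
        spike_idx = [i for i, sid in enumerate(members) if sid in spike_ids]
        if not spike_idx:
            continue
        if len(members) == 1:
            out[members[0]] = np.inf
            unchallenged += 1
            continue
        seqs = [junctions[sid] for sid in members]
        counts = pairwise_mismatches(seqs)
        for idxs in duplicate_index_sets(seqs):  # exact copies: distance 0
            counts[np.ix_(idxs, idxs)] = 0
        np.fill_diagonal(counts, np.iinfo(np.int64).max)
        length = group.key[2]
        for i in spike_idx:
            out[members[i]] = counts[i].min() / length
    total = len(out)
    return out, unchallenged / total if total else 0.0


def spike_in_specificity(
    design: SpikeInDesign,
    grid: np.ndarray | None = None,
    n_grid: int = DEFAULT_GRID_POINTS,
    family1: str = "gamma",
    family2: str = "gamma",
    v_level: str = "gene",
    j_level: str = "gene",
) -> PerformanceCurve:
    """Mean actual vs estimated specificity curves over spike-in replicates.

    Each replicate resamples one spike per foreign individual, merges them
    into the base repertoire, recomputes distance-to-nearest, refits the
    mixture, and evaluates: actual specificity = fraction of spikes that
    remain singleton clones at t; estimated specificity from the fitted
    component areas. Curves are averaged over replicates and compared by
    squared Pearson correlation.
    """
    base_ids = set(design.base.ids())
    rep_t1, rep_t2 = [], []
    rep_models: list[MixtureModel] = []
    rep_spike_dists: list[np.ndarray] = []
    unchallenged_fracs: list[float] = []
    for rep in range(design.n_reps):
        if design.foreign:
            spikes = sample_spikes(design.foreign, design.seed, rep)
        else:
            spikes = design.spikes
        clash = [s.sequence_id for s in spikes if s.sequence_id in base_ids]
        if clash:
            raise ConsistencyError(f"spike ids collide with base ids: {clash[:3]}")
        merged = Dataset(design.base.records + list(spikes), dialect=design.base.dialect)
        dtn = distance_to_nearest_of(merged, v_level, j_level)
        _, values = dtn.defined()
        model = fit_mixture(values, family1, family2, seed=design.seed)
        spike_ids = {s.sequence_id for s in spikes}
        dists, unchallenged = _spike_nearest_distances(merged, spike_ids, v_level, j_level)
        rep_models.append(model)
        rep_t1.append(float(values.min()))
        rep_t2.append(float(values.max()))
        rep_spike_dists.append(np.array([dists[sid] for sid in sorted(spike_ids)]))
        unchallenged_fracs.append(unchallenged)

    if grid is None:
        lo, hi = max(rep_t1), min(rep_t2)
        if not hi > lo:  # replicate ranges disjoint; fall back to the union
            lo, hi = min(rep_t1), max(rep_t2)
        grid = np.linspace(lo, hi, n_grid + 2)[1:-1]
    grid = np.asarray(grid, dtype=float)

    actual = np.zeros((design.n_reps, grid.size))
    est = np.zeros((design.n_reps, grid.size))
    for r in range(design.n_reps):
        actual[r] = (rep_spike_dists[r][:, None] >= grid[None, :]).mean(axis=0)
        _, est[r] = estimated_curves(rep_models[r], grid, rep_t1[r], rep_t2[r])
    mean_actual = actual.mean(axis=0)
    mean_est = est.mean(axis=0)
    r2 = squared_pearson(mean_actual, mean_est)
    return PerformanceCurve(
        grid=grid,
        actual_sen=None,
        actual_spc=mean_actual,
        est_sen=None,
        est_spc=mean_est,
        r2_sen=None,
        r2_spc=r2,
        diagnostics={
            "n_reps": design.n_reps,
            "unchallenged_fraction": float(np.mean(unchallenged_fracs)),
            "per_rep_r2": [
                squared_pearson(actual[r], est[r]) for r in range(design.n_reps)
            ],
        },
    )
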