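"""Evaluation machinery: error statistics, Bland–Altman agreement, the AAMI
accuracy criterion, subject-disjoint k-fold cross-validation and the
attention-weight analysis by blood-pressure group.

Sign convention: errors are estimated minus reference (yhat - y).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

__all__ = [
    "EvalReport",
    "FoldSplit",
    "error_stats",
    "bland_altman",
    "aami_check",
    "make_folds",
    "crossval",
    "attention_group_report",
    "scatter_plot",
    "bland_altman_plot",
]

AAMI_ME_LIMIT = 5.0  # mmHg, |mean error|
AAMI_STD_LIMIT = 8.0  # mmHg, error SD
LOA_FACTOR = 1.96

HYPERTENSIVE_SBP = 140.0
HYPERTENSIVE_DBP = 90.0
HYPOTENSIVE_SBP = 90.0
HYPOTENSIVE_DBP = 60.0


@dataclass
class EvalReport:
    """ME / STD / Pearson r plus Bland–Altman limits for one target."""

    target: str
    me: float
    std: float
    pearson_r: float | None
    bland_altman: tuple[float, float, float]  # mean diff, lower LoA, upper LoA
    aami_pass: bool
    n_cases: int

    def to_dict(self) -> dict:
        return asdict(self)


def error_stats(
    y_ref: np.ndarray, y_hat: np.ndarray
) -> tuple[float, float, float | None]:
    """Mean error, sample SD of the error (N-1) and Pearson r.

    Exact equality of the two vectors short-circuits to r = 1; otherwise a
    zero-variance vector leaves r undefined (returned as None).
    """
    y = np.asarray(y_ref, dtype=float)
    yh = np.asarray(y_hat, dtype=float)
    if y.shape != yh.shape or y.size < 2:
        raise ValueError("need two equal-length vectors with N >= 2")
    err = yh - y
    me = float(err.mean())
    std = float(err.std(ddof=1))
    if np.array_equal(y, yh):
        return me, std, 1.0
    if y.std() == 0.0 or yh.std() == 0.0:
        return me, std, None
    r = float(np.corrcoef(y, yh)[0, 1])
    return me, std, r


def bland_altman(
    y_ref: np.ndarray, y_hat: np.ndarray
) -> tuple[tuple[float, float, float], pd.DataFrame, float]:
    """Limits of agreement (mean diff +/- 1.96 SD), the per-case
    (mean, diff) pairs for plotting, and the fraction of cases inside the
    limits."""
    y = np.asarray(y_ref, dtype=float)
    yh = np.asarray(y_hat, dtype=float)
    if y.shape != yh.shape or y.size < 2:
        raise ValueError("need two equal-length vectors with N >= 2")
    diff = yh - y
    mean_diff = float(diff.mean())
    sd = float(diff.std(ddof=1))
    lower, upper = mean_diff - LOA_FACTOR * sd, mean_diff + LOA_FACTOR * sd
    pairs = pd.DataFrame({"mean": (y + yh) / 2.0, "diff": diff})
    inside = float(np.mean((diff >= lower) & (diff <= upper)))
    return (mean_diff, lower, upper), pairs, inside


def aami_check(me: float, std: float) -> bool:
    """Device-accuracy criterion: |ME| <= 5 mmHg and STD <= 8 mmHg
    (boundaries inclusive)."""
    return abs(me) <= AAMI_ME_LIMIT and std <= AAMI_STD_LIMIT


def make_report(target: str, y_ref: np.ndarray, y_hat: np.ndarray) -> EvalReport:
    me, std, r = error_stats(y_ref, y_hat)
    limits, _, _ = bland_altman(y_ref, y_hat)
    return EvalReport(
        target=target,
        me=me,
        std=std,
        pearson_r=r,
        bland_altman=limits,
        aami_pass=aami_check(me, std),
        n_cases=len(np.asarray(y_ref)),
    )


@dataclass
class FoldSplit:
    """Subject-level fold assignment; all of a subject's cases travel together."""

    assignments: dict[str, int]  # subject_id -> fold index (1-based)
    k: int

    def test_subjects(self, fold: int) -> set[str]:
        return {s for s, f in self.assignments.items() if f == fold}

    def train_subjects(self, fold: int) -> set[str]:
        return {s for s, f in self.assignments.items() if f != fold}


def make_folds(subject_ids, k: int = 5, seed: int = 0) -> FoldSplit:
    """Shuffle subjects with `seed` and partition into k near-equal folds."""
    subjects = list(dict.fromkeys(subject_ids))  # unique, order-preserving
    if len(subjects) < k:
        raise ValueError(f"{len(subjects)} subjects cannot fill {k} folds")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(subjects))
    assignments: dict[str, int] = {}
    for fold, chunk in enumerate(np.array_split(order, k), start=1):
        for i in chunk:
            assignments[subjects[i]] = fold
    return FoldSplit(assignments=assignments, k=k)


def crossval(dataset, model_recipe, k: int = 5, seed: int = 0):
    """Subject-disjoint k-fold cross-validation.

    ``model_recipe(train_set)`` must return an object with a
    ``predict_batch(dataset) -> (estimates, weights)`` method (weights may be
    None).  Returns (per-fold EvalReports, pooled EvalReport); the pooled
    statistics are computed over the concatenated held-out predictions, i.e.
    case-weighted.
    """
    split = make_folds(dataset.subject_ids, k=k, seed=seed)
    reports = []
    all_ref, all_hat = [], []
    target = None
    for fold in range(1, k + 1):
        test_subj = split.test_subjects(fold)
        test_idx = np.where(np.isin(dataset.subject_ids, list(test_subj)))[0]
        train_idx = np.where(~np.isin(dataset.subject_ids, list(test_subj)))[0]
        try:
            system = model_recipe(dataset.subset(train_idx))
        except Exception as err:
            raise RuntimeError(f"fold {fold}: training failed: {err}") from err
        test_set = dataset.subset(test_idx)
        y_hat, _ = system.predict_batch(test_set)
        target = system.target
        y_ref = test_set.labels(target)
        reports.append(make_report(target, y_ref, y_hat))
        all_ref.append(y_ref)
        all_hat.append(y_hat)
    pooled = make_report(target, np.concatenate(all_ref), np.concatenate(all_hat))
    return reports, pooled


def bp_group(sbp: float, dbp: float) -> str:
    """Clinical BP category from the reference readings (140/90 and 90/60
    mmHg thresholds)."""
    if sbp >= HYPERTENSIVE_SBP or dbp >= HYPERTENSIVE_DBP:
        return "hypertensive"
    if sbp <= HYPOTENSIVE_SBP or dbp <= HYPOTENSIVE_DBP:
        return "hypotensive"
    return "normotensive"


def attention_group_report(
    ref_sbp: np.ndarray, ref_dbp: np.ndarray, weights: np.ndarray
) -> dict[str, dict]:
    """Mean attention weight per channel within each BP group.

    Returns {group: {"n": count, "mean_weights": 9-vector or None}}; group
    means of simplex points stay on the simplex.
    """
    sbp = np.asarray(ref_sbp, dtype=float)
    dbp = np.asarray(ref_dbp, dtype=float)
    w = np.asarray(weights, dtype=float)
    if w.ndim != 2 or w.shape[0] != sbp.size or sbp.size == 0:
        raise ValueError("weights must be (n_cases, n_channels) matching the refs")
    groups = np.array([bp_group(s, d) for s, d in zip(sbp, dbp)])
    out: dict[str, dict] = {}
    for g in ("hypertensive", "hypotensive", "normotensive"):
        mask = groups == g
        out[g] = {
            "n": int(mask.sum()),
            "mean_weights": w[mask].mean(axis=0) if mask.any() else None,
        }
    return out


# ---------------------------------------------------------------------------
# Plots (smoke-level: agreement and correlation visuals)
# ---------------------------------------------------------------------------

def _agg_backend():
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    return plt


def scatter_plot(y_ref, y_hat, target: str, path) -> None:
    plt = _agg_backend()
    y = np.asarray(y_ref, float)
    yh = np.asarray(y_hat, float)
    _, _, r = error_stats(y, yh)
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.scatter(y, yh, s=8, alpha=0.6)
    lims = [min(y.min(), yh.min()) - 5, max(y.max(), yh.max()) + 5]
    ax.plot(lims, lims, "k--", lw=0.8)
    ax.set_xlabel(f"Reference {target} (mmHg)")
    ax.set_ylabel(f"Estimated {target} (mmHg)")
    ax.set_title(f"{target}: r = {r:.2f}" if r is not None else target)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def bland_altman_plot(y_ref, y_hat, target: str, path) -> None:
    plt = _agg_backend()
    (mean_diff, lower, upper), pairs, _ = bland_altman(y_ref, y_hat)
    fig, ax = plt.subplots(figsize=(4.5, 3.5))
    ax.scatter(pairs["mean"], pairs["diff"], s=8, alpha=0.6)
    for val, style in ((mean_diff, "-"), (lower, "--"), (upper, "--")):
        ax.axhline(val, color="r", ls=style, lw=0.8)
    ax.set_xlabel(f"Mean of reference and estimate (mmHg)")
    ax.set_ylabel("Difference (mmHg)")
    ax.set_title(f"{target} Bland–Altman")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
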