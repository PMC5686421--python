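"""Ranking metrics, the repeated-split protocol and significance testing.

Average precision is non-interpolated: the mean of precision-at-k over the
ranks k of the positive items, with ties broken deterministically.  AUC-ROC
equals the Mann-Whitney concordance probability, with tied scores counting
half per tied positive-negative pair (midranks).  Systems are compared with
the paired-samples t test on per-split scores.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .datatypes import ConfigurationError, DatasetSplit, EvalReport, SplitProtocol


def _ranked_labels(labels, scores, tie_keys=None) -> np.ndarray:
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    if labels.shape != scores.shape:
        raise ValueError("labels and scores must have equal length")
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    keys = np.arange(len(labels)) if tie_keys is None else np.asarray(tie_keys)
    # descending score; ties broken by ascending key (term string or index)
    order = np.lexsort((keys, -scores))
    return labels[order]


def average_precision(labels, scores, tie_keys=None) -> float:
    """Non-interpolated average precision of a scored ranking.

    ``tie_keys`` (e.g. term strings) break score ties by ascending key; by
    default input order breaks ties.  Requires at least one positive label.
    """
    ranked = _ranked_labels(labels, scores, tie_keys)
    P = int(ranked.sum())
    if P == 0:
        raise ConfigurationError("average precision undefined without positive labels")
    ks = np.flatnonzero(ranked == 1) + 1  # 1-based ranks of positives
    precision_at_pos = np.cumsum(ranked)[ks - 1] / ks
    return float(precision_at_pos.sum() / P)


def auc_roc(labels, scores) -> float:
    """Mann-Whitney AUC with the midrank convention for tied scores."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    if labels.shape != scores.shape:
        raise ValueError("labels and scores must have equal length")
    P = int((labels == 1).sum())
    N = int((labels == 0).sum())
    if P == 0 or N == 0:
        raise ConfigurationError("AUC-ROC requires both classes")
    ranks = stats.rankdata(scores)  # midranks
    r_pos = ranks[labels == 1].sum()
    return float((r_pos - P * (P + 1) / 2.0) / (P * N))


def paired_t_test(a, b) -> tuple[float, float, int]:
    """Two-sided paired-samples t test on per-split scores.

    Returns (t, p, df).  Zero-variance differences with nonzero mean yield a
    capped t and an underflow-safe minimal p; identical inputs yield
    (0, 1, n-1).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired t test needs equal-length score lists")
    n = len(a)
    if n < 2:
        raise ConfigurationError("paired t test needs n >= 2")
    d = a - b
    df = n - 1
    if np.allclose(d.std(ddof=1), 0.0):
        if np.allclose(d.mean(), 0.0):
            return 0.0, 1.0, df
        t_cap = np.sign(d.mean()) * 1e308
        return float(t_cap), float(np.finfo(float).tiny), df
    t, p = stats.ttest_rel(a, b)
    return float(t), float(p), df


def make_splits(annotated: list[tuple[str, int]], protocol: SplitProtocol) -> list[DatasetSplit]:
    """Repeated random subsampling: per repeat, draw a target pool without
    replacement and keep the remainder as the evaluation set; the pool is
    additionally shuffled so that the first L items form the size-L target
    training set.  Deterministic per (seed, repeat index)."""
    if len(annotated) <= protocol.target_pool_size:
        raise ConfigurationError(
            f"need more than target_pool_size={protocol.target_pool_size} annotated terms, "
            f"got {len(annotated)}"
        )
    splits = []
    for r in range(protocol.n_repeats):
        rng = np.random.default_rng([protocol.seed, r])
        perm = rng.permutation(len(annotated))
        pool_idx = perm[: protocol.target_pool_size]
        eval_idx = np.sort(perm[protocol.target_pool_size :])
        pool = [annotated[i] for i in pool_idx]
        splits.append(DatasetSplit(target_pool=pool, evaluation=[annotated[i] for i in eval_idx]))
    return splits


def evaluate_systems(
    systems: list[str],
    splits: list[DatasetSplit],
    raw_features: dict[str, np.ndarray],
    source_train: list[tuple[str, int]],
    transfer_cfg,
    L_values: tuple[int, ...] = (100,),
    standardize: bool = True,
    tune_per_split: bool = False,
) -> EvalReport:
    """Run the repeated-split protocol for each system and training size L.

    Per split and L: feature standardization is fitted on the union of
    source and target training terms, each system is trained, and AP /
    AUC-ROC are measured on the split's evaluation set.  Aggregates
    per-system means and pairwise paired t statistics on AP.

    Hyperparameters are grid-searched by cross-validation on target training
    data once per (system, L) — averaging the CV grid over the first ten
    splits — and reused across repeats, so that paired per-split differences
    reflect the systems rather than per-split selection jitter;
    ``tune_per_split=True`` re-tunes inside every split instead.
    """
    from .models import (
        _fit_system,
        grid_scores,
        predict_scores,
        select_from_grid,
        train_system,
    )

    report = EvalReport()
    src_terms = [t for t, _ in source_train]
    ys = np.array([l for _, l in source_train], dtype=float)
    Xs_raw = np.vstack([raw_features[t] for t in src_terms]) if src_terms else np.zeros((0, 1))

    def split_data(split: DatasetSplit, L: int):
        tt = split.target_train(L)
        yt = np.array([l for _, l in tt], dtype=float)
        Xt_raw = np.vstack([raw_features[t] for t, _ in tt])
        eval_terms = [t for t, _ in split.evaluation]
        y_eval = np.array([l for _, l in split.evaluation])
        Xe_raw = np.vstack([raw_features[t] for t in eval_terms])
        if not standardize:
            return Xs_raw, Xt_raw, Xe_raw, yt, y_eval, eval_terms
        train_X = np.vstack([Xs_raw, Xt_raw]) if len(src_terms) else Xt_raw
        mu = train_X.mean(axis=0)
        sd = train_X.std(axis=0, ddof=0)
        sd = np.where(sd > 0, sd, 1.0)
        Xs = (Xs_raw - mu) / sd if len(src_terms) else Xs_raw
        return Xs, (Xt_raw - mu) / sd, (Xe_raw - mu) / sd, yt, y_eval, eval_terms

    tuned: dict[tuple[str, int], tuple[float, float | None]] = {}
    if not tune_per_split:
        for L in L_values:
            tables: dict[str, list[dict]] = {s: [] for s in systems}
            for split in splits[: min(10, len(splits))]:
                Xs, Xt, _Xe, yt, _ye, _et = split_data(split, L)
                for system in systems:
                    tables[system].append(
                        grid_scores(system, Xs, ys, Xt, yt, transfer_cfg)
                    )
            for system in systems:
                keys = set().union(*tables[system])
                avg = {
                    k: float(np.mean([t[k] for t in tables[system] if k in t]))
                    for k in keys
                }
                tuned[(system, L)] = select_from_grid(avg)

    for r, split in enumerate(splits):
        for L in L_values:
            Xs, Xt, Xe, yt, y_eval, eval_terms = split_data(split, L)
            for system in systems:
                if tune_per_split:
                    model = train_system(system, Xs, ys, Xt, yt, transfer_cfg)
                else:
                    C, beta = tuned[(system, L)]
                    model = _fit_system(system, Xs, ys, Xt, yt, C, beta)
                scores = predict_scores(model, Xe)
                ap = average_precision(y_eval, scores, tie_keys=np.array(eval_terms))
                auc = auc_roc(y_eval, scores)
                report.per_split.append((system, L, r, ap, auc))
    for system in systems:
        for L in L_values:
            report.means[(system, L)] = (
                float(np.mean(report.scores(system, L, "ap"))),
                float(np.mean(report.scores(system, L, "auc"))),
            )
    for i, a in enumerate(systems):
        for b in systems[i + 1 :]:
            for L in L_values:
                sa = report.scores(a, L, "ap")
                sb = report.scores(b, L, "ap")
                if len(sa) >= 2:
                    report.paired_t[((a, L), (b, L))] = paired_t_test(sa, sb)
    return report
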