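"""Stage 2 of feature selection: random-forest panel construction.

Given the candidate CpGs from the differential filter, a panel is built in
two steps, repeated over several seeded runs:

1. rank candidates by out-of-bag (OOB) permutation importance (mean
   decrease in accuracy) of a random forest trained on all candidates;
2. forward-select features in rank order, accepting a feature only when
   retraining the forest on the enlarged set strictly reduces the
   aggregated OOB error (optionally by more than ``min_improve``).

Each run contributes its top features; the union over runs is re-ranked by
a final forest and truncated to the panel size. Forest defaults follow the
randomForest convention: 500 trees, node size 1, mtry = floor(sqrt(p))
recomputed whenever the feature count changes.

OOB machinery: scikit-learn draws each tree's bootstrap as
``randint(0, n, n)`` from the tree's seeded RNG, so the OOB rows of every
tree are reconstructed here exactly without refitting; the aggregated OOB
prediction is the per-sample majority vote over trees in which the sample
was out of bag.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.utils import check_random_state

from .diffmeth import FilterConfig, select_candidate_cpgs
from .matrix import BetaMatrix, SampleLabels

__all__ = [
    "RFParams",
    "ImportanceRanking",
    "SelectionRun",
    "PanelSelection",
    "oob_permutation_importance",
    "oob_forward_selection",
    "run_panel_selection",
    "sweep_panel_size",
]


@dataclass(frozen=True)
class RFParams:
    ntree: int = 500
    node_size: int = 1
    #: features tried per split; None = floor(sqrt(p)) at each retrain
    mtry: int | None = None
    seed: int = 0

    def __post_init__(self):
        if self.ntree < 1:
            raise ValueError("ntree must be >= 1")
        if self.node_size < 1:
            raise ValueError("node_size must be >= 1")

    def max_features(self, p: int):
        if self.mtry is None:
            return "sqrt"  # sklearn: max(1, int(sqrt(p)))
        if not (1 <= self.mtry <= p):
            raise ValueError(f"mtry must be in [1, {p}]")
        return self.mtry


@dataclass(frozen=True)
class ImportanceRanking:
    """Probes ordered by OOB permutation importance.

    Descending score; ties broken by probe id ascending so rankings are
    deterministic across platforms.
    """

    table: pd.DataFrame  # index = probe_id, column "importance", sorted

    @property
    def probes(self) -> list[str]:
        return list(self.table.index)

    def top(self, k: int) -> list[str]:
        return list(self.table.index[:k])

    def __len__(self) -> int:
        return len(self.table)


@dataclass(frozen=True)
class SelectionRun:
    seed: int
    ranking: ImportanceRanking
    kept: list[str]
    #: aggregated OOB error after the initial feature and each acceptance
    oob_trace: list[float]
    n_evaluated: int = 0


@dataclass(frozen=True)
class PanelSelection:
    runs: list[SelectionRun]
    per_run_top: list[list[str]]
    union: list[str]
    final_ranking: ImportanceRanking
    panel: list[str]
    params: dict = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def to_tsv(self, path) -> None:
        t = self.final_ranking.table.copy()
        for r, top in enumerate(self.per_run_top):
            t[f"run{r}"] = t.index.isin(top)
        t["in_final"] = t.index.isin(self.panel)
        t.to_csv(path, sep="\t", index_label="probe_id")


# ---------------------------------------------------------------------------
# OOB plumbing
# ---------------------------------------------------------------------------

def _encode(labels: SampleLabels, sample_ids):
    y = labels.for_samples(sample_ids)
    classes = sorted(np.unique(y))
    code = {c: i for i, c in enumerate(classes)}
    return np.array([code[c] for c in y]), classes


def _design(bm: BetaMatrix, features) -> np.ndarray:
    x = bm.data[list(features)].to_numpy(dtype=float)
    if np.isnan(x).any():
        raise ValueError(
            "matrix has missing values; harmonize/impute before selection")
    return x


def _fit_forest(x, y, rf: RFParams, seed=None) -> RandomForestClassifier:
    forest = RandomForestClassifier(
        n_estimators=rf.ntree,
        min_samples_leaf=rf.node_size,
        max_features=rf.max_features(x.shape[1]),
        bootstrap=True,
        random_state=rf.seed if seed is None else seed,
        n_jobs=1,
    )
    forest.fit(x, y)
    return forest


def _oob_rows(tree_random_state: int, n_samples: int) -> np.ndarray:
    """Rows left out of one tree's bootstrap (mirrors sklearn's draw)."""
    rng = check_random_state(tree_random_state)
    sampled = rng.randint(0, n_samples, n_samples)
    mask = np.ones(n_samples, dtype=bool)
    mask[sampled] = False
    return np.nonzero(mask)[0]


def oob_error(forest: RandomForestClassifier, x: np.ndarray,
              y: np.ndarray) -> float:
    """Aggregated OOB misclassification rate (majority vote over trees)."""
    n = x.shape[0]
    k = len(forest.classes_)
    votes = np.zeros((n, k))
    for tree in forest.estimators_:
        oob = _oob_rows(tree.random_state, n)
        if oob.size == 0:
            continue
        pred = tree.predict(x[oob]).astype(int)
        votes[oob, pred] += 1
    voted = votes.sum(axis=1) > 0
    pred = votes.argmax(axis=1)  # ties -> lowest class code
    return float(np.mean(pred[voted] != y[voted])) if voted.any() else 1.0


def oob_permutation_importance(bm: BetaMatrix, labels: SampleLabels,
                               features, rf: RFParams) -> ImportanceRanking:
    """Mean decrease in accuracy, estimated on each tree's OOB samples.

    For every tree and feature: the feature's values are permuted among
    the tree's OOB samples and the rise in that tree's OOB error is
    recorded; the importance is the average rise over trees. Features
    unrelated to the labels score ~0; zero-variance features score
    exactly 0.
    """
    features = list(features)
    x = _design(bm, features)
    y, _ = _encode(labels, bm.sample_ids)
    if np.min(np.bincount(y)) < 2:
        raise ValueError("every class needs >=2 samples")
    forest = _fit_forest(x, y, rf)
    nf = len(features)
    rng = np.random.default_rng(rf.seed)
    imp = np.zeros(nf)
    n = x.shape[0]
    for tree in forest.estimators_:
        oob = _oob_rows(tree.random_state, n)
        m = oob.size
        if m == 0:
            continue
        xo = x[oob]
        yo = y[oob]
        base_err = np.mean(tree.predict(xo).astype(int) != yo)
        # one permutation per feature, drawn as argsorted random keys
        perm = np.argsort(rng.random((nf, m)), axis=1)
        stack = np.broadcast_to(xo, (nf, m, nf)).copy()
        idx = np.arange(nf)
        stack[idx, :, idx] = np.take_along_axis(
            xo.T, perm, axis=1)  # feature j permuted in copy j
        preds = tree.predict(stack.reshape(nf * m, nf)).astype(int)
        errs = (preds.reshape(nf, m) != yo).mean(axis=1)
        imp += errs - base_err
    imp /= len(forest.estimators_)
    order = np.lexsort((np.array(features), -imp))
    table = pd.DataFrame(
        {"importance": imp[order]},
        index=pd.Index(np.array(features)[order], name="probe_id"))
    return ImportanceRanking(table)


def oob_forward_selection(bm: BetaMatrix, labels: SampleLabels,
                          ranking: ImportanceRanking, rf: RFParams,
                          min_improve: float = 0.0) -> SelectionRun:
    """Forward inclusion in importance order, guided by aggregated OOB error.

    The kept set starts with the top-ranked feature; each subsequent
    candidate is accepted iff retraining on ``kept + {candidate}`` lowers
    the OOB error by more than ``min_improve``. The trace of errors at
    accepted steps is strictly decreasing by construction. Evaluation
    stops early once the current error can no longer strictly improve
    (error <= min_improve), which changes no decision.
    """
    ranked = ranking.probes
    if not ranked:
        raise ValueError("empty ranking")
    y, _ = _encode(labels, bm.sample_ids)
    kept = [ranked[0]]
    err = oob_error(_fit_forest(_design(bm, kept), y, rf), _design(bm, kept), y)
    trace = [err]
    n_eval = 0
    for cand in ranked[1:]:
        if err <= min_improve:  # strict decrease now impossible
            break
        n_eval += 1
        x_new = _design(bm, kept + [cand])
        new_err = oob_error(_fit_forest(x_new, y, rf), x_new, y)
        if new_err < err - min_improve:
            kept.append(cand)
            err = new_err
            trace.append(err)
    return SelectionRun(seed=rf.seed, ranking=ranking, kept=kept,
                        oob_trace=trace, n_evaluated=n_eval)


def run_panel_selection(bm: BetaMatrix, labels: SampleLabels,
                        filter_cfg: FilterConfig = FilterConfig(),
                        rf: RFParams = RFParams(),
                        n_runs: int = 5, per_run_top: int = 200,
                        final_k: int = 200,
                        rank_source: str = "all_candidates",
                        min_improve: float = 0.0,
                        candidates=None) -> PanelSelection:
    """Full two-step panel construction over ``n_runs`` seeded runs.

    Each run uses forest seed ``rf.seed + run_index`` over the candidate
    set from the differential filter (runs re-randomize only the forest).
    ``rank_source`` controls where a run's top features are drawn from:

    - ``all_candidates`` (default): the run's importance ranking over all
      candidates;
    - ``kept``: the importance ranking of a forest retrained on the run's
      forward-selected kept set (runs may then contribute fewer than
      ``per_run_top`` features).

    The union of per-run top sets is re-ranked by a forest seeded with
    ``rf.seed`` and truncated to ``final_k``.
    """
    if rank_source not in ("all_candidates", "kept"):
        raise ValueError(f"unknown rank_source {rank_source!r}")
    warns = []
    if candidates is None:
        candidates = select_candidate_cpgs(bm, labels, filter_cfg).candidates
    candidates = list(candidates)
    if not candidates:
        raise ValueError("candidate filter produced no probes")
    if len(candidates) < final_k:
        warns.append(f"only {len(candidates)} candidates for final_k="
                     f"{final_k}; proceeding with all")

    runs, tops = [], []
    for r in range(n_runs):
        rf_r = replace(rf, seed=rf.seed + r)
        ranking = oob_permutation_importance(bm, labels, candidates, rf_r)
        run = oob_forward_selection(bm, labels, ranking, rf_r, min_improve)
        runs.append(run)
        if rank_source == "all_candidates":
            tops.append(ranking.top(per_run_top))
        else:
            kept_rank = oob_permutation_importance(
                bm, labels, run.kept, rf_r)
            tops.append(kept_rank.top(per_run_top))

    union = sorted(set().union(*map(set, tops)))
    final_ranking = oob_permutation_importance(bm, labels, union, rf)
    if len(union) < final_k:
        warns.append(f"union has {len(union)} probes < final_k={final_k}; "
                     "panel truncated to the union")
    panel = final_ranking.top(final_k)
    for w in warns:
        warnings.warn(w, stacklevel=2)
    return PanelSelection(
        runs=runs, per_run_top=tops, union=union,
        final_ranking=final_ranking, panel=panel,
        params={"n_runs": n_runs, "per_run_top": per_run_top,
                "final_k": final_k, "rank_source": rank_source,
                "min_improve": min_improve, "base_seed": rf.seed,
                "run_seeds": [rf.seed + r for r in range(n_runs)],
                "ntree": rf.ntree, "node_size": rf.node_size},
        warnings=warns)


def sweep_panel_size(bm_train: BetaMatrix, labels_train: SampleLabels,
                     bm_valid: BetaMatrix, labels_valid: SampleLabels,
                     ranking: ImportanceRanking,
                     ks=(50, 100, 150, 200, 250, 300),
                     algorithm: str = "en", cfg=None) -> pd.DataFrame:
    """Validation accuracy of classifiers trained on top-k panels.

    Values of k exceeding the available ranked features are skipped with
    a warning. Returns a frame with columns k, n_features, accuracy.
    """
    from .models import predict, train_classifier  # deferred: avoids cycle

    rows = []
    for k in ks:
        if k > len(ranking):
            warnings.warn(f"k={k} exceeds {len(ranking)} ranked features; "
                          "skipped", stacklevel=2)
            continue
        top = ranking.top(k)
        model = train_classifier(bm_train.subset_probes(top), labels_train,
                                 algorithm=algorithm, cfg=cfg)
        pred = predict(model, bm_valid.subset_probes(top))
        acc = float(np.mean(
            pred.predicted.to_numpy()
            == labels_valid.for_samples(bm_valid.sample_ids)))
        rows.append((k, len(top), acc))
    return pd.DataFrame(rows, columns=["k", "n_features", "accuracy"])
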