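"""Stage 1 of feature selection: per-CpG differential methylation.

For every probe, a one-way ANOVA compares beta values across cancer-type
classes; Tukey's honestly-significant-difference post hoc test is then
applied to probes with a significant ANOVA, using the Tukey-Kramer
standard error for unequal class sizes. A probe becomes a candidate when
it is differentially methylated in at least one class: under the default
``one_vs_all`` criterion there must exist a class c whose mean differs
from every other class d with Tukey-adjusted p < alpha and
|delta-beta| > delta; ``any_pair`` requires only a single such pair.

Tests are computed on beta values directly with per-probe complete-case
handling of missing data. No multiple-testing correction is applied across
probes; thresholds are per-probe.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .matrix import BetaMatrix, SampleLabels

__all__ = [
    "FilterConfig",
    "DiffMethResult",
    "one_way_anova",
    "tukey_hsd",
    "select_candidate_cpgs",
]


@dataclass(frozen=True)
class FilterConfig:
    #: minimum absolute group-mean beta difference
    delta: float = 0.2
    #: per-probe significance level for ANOVA and Tukey-adjusted p
    alpha: float = 0.01
    criterion: str = "one_vs_all"

    def __post_init__(self):
        if not (0 < self.delta < 1):
            raise ValueError("delta must be in (0, 1)")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        if self.criterion not in ("one_vs_all", "any_pair"):
            raise ValueError(f"unknown criterion {self.criterion!r}")


@dataclass(frozen=True)
class DiffMethResult:
    """Per-probe ANOVA/Tukey results and the candidate pass flags.

    ``table`` has one row per probe: F, p_anova, pass flag, qualifying
    class (one_vs_all), max |delta-beta| and min adjusted p over the
    relevant pairs, and an ``evaluable`` flag. ``pairwise`` holds the
    per-class-pair delta-beta and Tukey-adjusted p for every probe on
    which the post hoc test was run (probes failing ANOVA carry no rows).
    """

    table: pd.DataFrame
    pairwise: pd.DataFrame
    classes: list[str] = field(default_factory=list)
    config: FilterConfig = FilterConfig()

    @property
    def candidates(self) -> list[str]:
        t = self.table
        return list(t.index[t["pass"]])

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", na_rep="NA",
                          index_label="probe_id")


def _group_arrays(values, labels: SampleLabels):
    """Split one probe's values by class, dropping missing entries."""
    s = pd.Series(values)
    y = labels.for_samples(s.index)
    groups = []
    for c in sorted(np.unique(y)):
        g = s.to_numpy(dtype=float)[y == c]
        groups.append(g[~np.isnan(g)])
    return sorted(np.unique(y)), groups


def one_way_anova(values: pd.Series, labels: SampleLabels):
    """One-way fixed-effects ANOVA for a single probe.

    Returns ``(F, p)`` where F is the ratio of between-group to
    within-group mean squares and p comes from the F distribution with
    (k-1, N-k) degrees of freedom. Returns ``(nan, nan)`` when any class
    has fewer than two usable samples or when the statistic is degenerate
    (zero within- and between-group variance).
    """
    _, groups = _group_arrays(values, labels)
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        return np.nan, np.nan
    ns = np.array([len(g) for g in groups], dtype=float)
    means = np.array([g.mean() for g in groups])
    grand = np.concatenate(groups).mean()
    n_total = ns.sum()
    k = len(groups)
    ssb = float((ns * (means - grand) ** 2).sum())
    ssw = float(sum(((g - m) ** 2).sum() for g, m in zip(groups, means)))
    dfb, dfw = k - 1, n_total - k
    if ssw == 0.0:
        if ssb == 0.0:
            return np.nan, np.nan  # all values identical: 0/0
        return np.inf, 0.0  # perfect separation
    f = (ssb / dfb) / (ssw / dfw)
    return f, float(stats.f.sf(f, dfb, dfw))


def tukey_hsd(values: pd.Series, labels: SampleLabels) -> pd.DataFrame:
    """Tukey HSD post hoc test for a single probe.

    Returns a frame with one row per class pair (a, b), a < b: the mean
    difference ``delta_beta = mean_a - mean_b`` and the adjusted p from
    the studentized range distribution with k groups and N-k df, using
    the Tukey-Kramer standard error ``sqrt(MSW/2 * (1/n_a + 1/n_b))``.
    """
    names, groups = _group_arrays(values, labels)
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("Tukey HSD needs >=2 classes with >=2 samples each")
    ns = np.array([len(g) for g in groups], dtype=float)
    means = np.array([g.mean() for g in groups])
    ssw = sum(((g - m) ** 2).sum() for g, m in zip(groups, means))
    k, n_total = len(groups), ns.sum()
    dfw = n_total - k
    msw = ssw / dfw
    rows = []
    for a, b in itertools.combinations(range(k), 2):
        diff = means[a] - means[b]
        se = np.sqrt(msw / 2.0 * (1.0 / ns[a] + 1.0 / ns[b]))
        if se == 0.0:
            p_adj = np.nan if diff == 0 else 0.0
        else:
            q = abs(diff) / se
            p_adj = float(stats.studentized_range.sf(q, k, dfw))
        rows.append((names[a], names[b], diff, p_adj))
    return pd.DataFrame(rows,
                        columns=["class_a", "class_b", "delta_beta", "p_adj"])


# ---------------------------------------------------------------------------
# Vectorized whole-matrix filter
# ---------------------------------------------------------------------------

def _vectorized_anova(x: np.ndarray, y_codes: np.ndarray, k: int):
    """ANOVA statistics for every probe at once.

    ``x`` is samples x probes with NaN, ``y_codes`` integer class codes.
    Returns per-probe arrays (F, p, evaluable) plus per-(class, probe)
    counts and means and the pooled within-group mean square, for reuse by
    the Tukey step.
    """
    p = x.shape[1]
    ok = ~np.isnan(x)
    counts = np.zeros((k, p))
    sums = np.zeros((k, p))
    sumsq = np.zeros((k, p))
    x0 = np.where(ok, x, 0.0)
    for c in range(k):
        rows = y_codes == c
        counts[c] = ok[rows].sum(axis=0)
        sums[c] = x0[rows].sum(axis=0)
        sumsq[c] = (x0[rows] ** 2).sum(axis=0)
    evaluable = (counts >= 2).all(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        means = sums / counts
        n_total = counts.sum(axis=0)
        grand = sums.sum(axis=0) / n_total
        ssb = (counts * (means - grand) ** 2).sum(axis=0)
        # within-group SS via sum(x^2) - n * mean^2, summed over classes
        ssw = (sumsq - counts * means ** 2).sum(axis=0)
        ssw = np.maximum(ssw, 0.0)  # guard tiny negative round-off
        dfw = n_total - k
        msw = ssw / dfw
        f = (ssb / (k - 1)) / msw
    pval = np.full(p, np.nan)
    finite = evaluable & np.isfinite(f)
    pval[finite] = stats.f.sf(f[finite], k - 1, dfw[finite])
    # perfect separation: ssw == 0, ssb > 0
    perfect = evaluable & (ssw == 0) & (ssb > 0)
    f[perfect] = np.inf
    pval[perfect] = 0.0
    degenerate = evaluable & (ssw == 0) & (ssb == 0)
    f[degenerate] = np.nan
    pval[degenerate] = np.nan
    return f, pval, evaluable, counts, means, msw, dfw


def select_candidate_cpgs(bm: BetaMatrix, labels: SampleLabels,
                          cfg: FilterConfig = FilterConfig()
                          ) -> DiffMethResult:
    """Run the two-stage differential filter over every probe.

    The post hoc test is only evaluated for probes whose ANOVA p-value is
    below ``cfg.alpha`` (it cannot change the pass decision elsewhere).
    """
    shared = [s for s in bm.sample_ids if s in set(labels.sample_ids)]
    if not shared:
        raise ValueError("no samples shared between matrix and labels")
    data = bm.data.loc[shared]
    y = labels.for_samples(shared)
    classes = sorted(np.unique(y))
    k = len(classes)
    if k < 2:
        raise ValueError("need >=2 classes")
    code = {c: i for i, c in enumerate(classes)}
    y_codes = np.array([code[c] for c in y])
    x = data.to_numpy(dtype=float)
    probes = np.array(bm.probe_ids)

    f, pval, evaluable, counts, means, msw, dfw = _vectorized_anova(
        x, y_codes, k)

    sig = evaluable & (pval < cfg.alpha)
    pairs = list(itertools.combinations(range(k), 2))
    pair_rows = []
    passed = np.zeros(len(probes), dtype=bool)
    qual = np.full(len(probes), None, dtype=object)
    max_dbeta = np.full(len(probes), np.nan)
    min_padj = np.full(len(probes), np.nan)

    sig_idx = np.nonzero(sig)[0]
    if sig_idx.size:
        m = means[:, sig_idx]  # k x s
        n = counts[:, sig_idx]
        msw_s = msw[sig_idx]
        dfw_s = dfw[sig_idx]
        n_pairs = len(pairs)
        diffs = np.empty((n_pairs, sig_idx.size))
        qstat = np.empty_like(diffs)
        for pi, (a, b) in enumerate(pairs):
            diffs[pi] = m[a] - m[b]
            se = np.sqrt(msw_s / 2.0 * (1.0 / n[a] + 1.0 / n[b]))
            with np.errstate(divide="ignore", invalid="ignore"):
                qstat[pi] = np.abs(diffs[pi]) / se
        padj = np.ones_like(qstat)
        finite_q = np.isfinite(qstat) & (qstat > 0)
        if finite_q.any():
            dfg = np.broadcast_to(dfw_s, qstat.shape)
            padj[finite_q] = stats.studentized_range.sf(
                qstat[finite_q], k, dfg[finite_q])
        padj[np.isinf(qstat)] = 0.0

        # per-pair significance under both thresholds
        pair_ok = (padj < cfg.alpha) & (np.abs(diffs) > cfg.delta)
        # class-vs-all matrix: ok_ca[c, s] = pair (c, d) ok for every d
        ok_ca = np.ones((k, sig_idx.size), dtype=bool)
        for pi, (a, b) in enumerate(pairs):
            ok_ca[a] &= pair_ok[pi]
            ok_ca[b] &= pair_ok[pi]
        for si, j in enumerate(sig_idx):
            max_dbeta[j] = np.nanmax(np.abs(diffs[:, si]))
            min_padj[j] = np.nanmin(padj[:, si])
            if cfg.criterion == "one_vs_all":
                winners = np.nonzero(ok_ca[:, si])[0]
                if winners.size:
                    passed[j] = True
                    qual[j] = classes[winners[0]]
            else:
                passed[j] = bool(pair_ok[:, si].any())
        for pi, (a, b) in enumerate(pairs):
            pair_rows.append(pd.DataFrame({
                "probe_id": probes[sig_idx],
                "class_a": classes[a],
                "class_b": classes[b],
                "delta_beta": diffs[pi],
                "p_adj": padj[pi],
            }))

    table = pd.DataFrame({
        "F": f,
        "p_anova": pval,
        "evaluable": evaluable,
        "pass": passed,
        "qualifying_class": qual,
        "max_abs_delta_beta": max_dbeta,
        "min_p_adj": min_padj,
    }, index=pd.Index(probes, name="probe_id"))
    pairwise = (pd.concat(pair_rows, ignore_index=True)
                if pair_rows else pd.DataFrame(
                    columns=["probe_id", "class_a", "class_b",
                             "delta_beta", "p_adj"]))
    if not passed.any():
        warnings.warn("no probe passed the candidate filter", stacklevel=2)
    return DiffMethResult(table=table, pairwise=pairwise,
                          classes=classes, config=cfg)
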