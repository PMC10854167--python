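"""Synthetic multi-class methylation cohorts with known ground truth.

Emulates the structure a differential-methylation filter and a
tissue-of-origin classifier exploit in real array data: a bimodal
background (most CpGs are either stably unmethylated or stably methylated),
class-specific differentially methylated probes planted with a fixed mean
beta shift, bounded heteroscedastic per-sample noise, optional missingness,
platform probe dropout, and count-level targeted bisulfite sequencing data.

Per-sample beta values are drawn from a Beta distribution parameterized by
mean m and precision phi (shape a = m*phi, b = (1-m)*phi), the standard
mean-precision model for bounded methylation fractions; phi = 30 gives
SD ~ 0.09 at m = 0.5 and smaller near the boundaries, comparable to array
noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrix import BetaMatrix, ProbeManifest, SampleLabels

__all__ = [
    "SimConfig",
    "SimTruth",
    "generate_beta_dataset",
    "apply_platform_dropout",
    "simulate_bisulfite_counts",
]

# planted class means are clipped into this range so Beta draws stay proper
_MEAN_LO, _MEAN_HI = 0.02, 0.98


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one synthetic cohort; the seed fully determines output."""

    n_classes: int = 8
    samples_per_class: int = 40
    n_probes: int = 5000
    informative_per_class: int = 20
    #: mean beta shift applied to a planted probe in its class (0 = null data)
    effect_delta: float = 0.35
    #: concentration of the per-sample Beta noise (larger = less noise)
    precision: float = 30.0
    #: fraction of background probes with a high (~0.85) baseline
    bimodal_mix: float = 0.4
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.effect_delta < 1):
            raise ValueError("effect_delta must be in [0, 1)")
        if self.informative_per_class * self.n_classes > self.n_probes:
            raise ValueError(
                "informative_per_class * n_classes exceeds n_probes")
        if self.precision <= 0:
            raise ValueError("precision must be positive")
        if not (0 <= self.bimodal_mix <= 1):
            raise ValueError("bimodal_mix must be in [0, 1]")
        if not (0 <= self.missing_rate < 1):
            raise ValueError("missing_rate must be in [0, 1)")


@dataclass(frozen=True)
class SimTruth:
    """Ground truth of a simulated cohort."""

    #: class name -> list of probe ids planted as informative for that class
    planted: dict = field(default_factory=dict)
    #: per-probe baseline mean beta
    baseline_mean: pd.Series = None
    #: (class, probe) -> shifted mean for planted probes only
    shifted_mean: pd.DataFrame = None

    @property
    def all_planted(self) -> list[str]:
        out = []
        for probes in self.planted.values():
            out.extend(probes)
        return sorted(out)


def _beta_draw(rng: np.random.Generator, mean: np.ndarray,
               precision: float) -> np.ndarray:
    mean = np.clip(mean, _MEAN_LO, _MEAN_HI)
    return rng.beta(mean * precision, (1.0 - mean) * precision)


def generate_beta_dataset(cfg: SimConfig):
    """Generate one cohort.

    Returns ``(BetaMatrix, SampleLabels, SimTruth, ProbeManifest)``.

    Background probe j has a baseline mean drawn from a low/high mixture
    (means ~0.15 / ~0.85, matching global array bimodality). For each class
    c, ``informative_per_class`` disjoint probes are shifted by
    ``effect_delta`` in class c only, with the sign chosen to keep the mean
    in range (preferring hypermethylation). The manifest spreads probes
    round-robin across 22 autosomes at 1 kb spacing.
    """
    rng = np.random.default_rng(cfg.seed)
    k, npc, p = cfg.n_classes, cfg.samples_per_class, cfg.n_probes

    probe_ids = np.array([f"cg{j:08d}" for j in range(p)])
    classes = [f"class{c + 1:02d}" for c in range(k)]
    sample_ids = [f"S{i:04d}" for i in range(k * npc)]
    y = np.repeat(np.arange(k), npc)

    # bimodal baseline means
    high = rng.random(p) < cfg.bimodal_mix
    base = np.where(
        high,
        _beta_draw(rng, np.full(p, 0.85), 20.0),
        _beta_draw(rng, np.full(p, 0.15), 20.0),
    )
    base = np.clip(base, _MEAN_LO, _MEAN_HI)

    # disjoint planted sets, one per class
    n_planted = k * cfg.informative_per_class
    planted_idx = rng.choice(p, size=n_planted, replace=False)
    planted = {}
    class_mean = np.tile(base, (k, 1))
    shifted_records = {}
    for c in range(k):
        idx = planted_idx[c * cfg.informative_per_class:
                          (c + 1) * cfg.informative_per_class]
        planted[classes[c]] = sorted(probe_ids[idx])
        up = base[idx] + cfg.effect_delta <= _MEAN_HI
        shifted = np.where(up, base[idx] + cfg.effect_delta,
                           base[idx] - cfg.effect_delta)
        shifted = np.clip(shifted, _MEAN_LO, _MEAN_HI)
        class_mean[c, idx] = shifted
        for pid, m in zip(probe_ids[idx], shifted):
            shifted_records[(classes[c], pid)] = m

    values = np.empty((k * npc, p))
    for c in range(k):
        rows = slice(c * npc, (c + 1) * npc)
        values[rows] = _beta_draw(
            rng, np.tile(class_mean[c], (npc, 1)), cfg.precision)

    if cfg.missing_rate > 0:
        mask = rng.random(values.shape) < cfg.missing_rate
        values[mask] = np.nan

    bm = BetaMatrix(pd.DataFrame(values, index=sample_ids, columns=probe_ids))
    labels = SampleLabels(pd.Series([classes[c] for c in y],
                                    index=sample_ids))
    shifted_df = pd.Series(shifted_records).rename("mean").reset_index()
    shifted_df.columns = ["class", "probe_id", "mean"]
    truth = SimTruth(
        planted=planted,
        baseline_mean=pd.Series(base, index=probe_ids),
        shifted_mean=shifted_df,
    )

    chroms = [f"chr{(j % 22) + 1}" for j in range(p)]
    positions = [10_000 + (j // 22) * 1_000 for j in range(p)]
    manifest = ProbeManifest(pd.DataFrame(
        {"chrom": chroms, "position": positions, "strand": "+"},
        index=pd.Index(probe_ids, name="probe_id")))
    return bm, labels, truth, manifest


def apply_platform_dropout(bm: BetaMatrix, keep_fraction: float,
                           seed: int) -> BetaMatrix:
    """Remove a seeded uniform sample of probes, emulating 450K/EPIC
    probe-set mismatch. Keeps ``ceil(keep_fraction * n_probes)`` probes in
    their original order."""
    if not (0 < keep_fraction <= 1):
        raise ValueError("keep_fraction must be in (0, 1]")
    probes = bm.probe_ids
    n_keep = int(np.ceil(keep_fraction * len(probes)))
    if n_keep == len(probes):
        return bm
    rng = np.random.default_rng(seed)
    keep_idx = np.sort(rng.choice(len(probes), size=n_keep, replace=False))
    return bm.subset_probes([probes[i] for i in keep_idx])


def simulate_bisulfite_counts(bm: BetaMatrix, manifest: ProbeManifest,
                              mean_coverage: float, seed: int) -> dict:
    """Simulate targeted bisulfite sequencing counts for every sample.

    Per (sample, probe): total coverage ~ max(1, Poisson(mean_coverage));
    methylated count ~ Binomial(coverage, beta). Probes with missing beta
    are omitted for that sample. Returns ``{sample_id: DataFrame}`` where
    each frame has columns chrom, position, strand, count_methylated,
    count_unmethylated (1-based CpG cytosine positions).
    """
    if mean_coverage < 1:
        raise ValueError("mean_coverage must be >= 1")
    rng = np.random.default_rng(seed)
    coords = manifest.coordinates(bm.probe_ids)
    out = {}
    vals = bm.data.to_numpy()
    for i, sample in enumerate(bm.sample_ids):
        beta = vals[i]
        ok = ~np.isnan(beta)
        cov = np.maximum(1, rng.poisson(mean_coverage, size=int(ok.sum())))
        meth = rng.binomial(cov, beta[ok])
        sub = coords.loc[ok]
        out[sample] = pd.DataFrame({
            "chrom": sub["chrom"].to_numpy(),
            "position": sub["position"].to_numpy(),
            "strand": sub["strand"].to_numpy(),
            "count_methylated": meth,
            "count_unmethylated": cov - meth,
        })
    return out
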