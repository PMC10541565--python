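"""Synthetic fruit-development expression data with known latent structure.

Emulates the training design of the method: two cultivars observed over
three vintages, 10-14 roughly weekly timepoints per series, three
replicates, RPKM-like values.  A shared latent developmental trajectory
(double sigmoid in days: slow start, a rapid mid-development onset, slow
end) is shifted in time per vintage and per cultivar; each non-noise gene
reads the latent stage through one of four archetype profiles scaled by a
lognormal baseline; replicates add mean-preserving multiplicative
lognormal noise.  Noise genes have exchangeable condition means with no
time trend.  The returned truth object carries everything needed to score
recovery: per-condition latent stage, per-gene archetypes, and the
planted rapid-transition window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .types import ExpressionTensor, SampleMeta

__all__ = ["SyntheticTruth", "generate_dataset", "generate_reference_panel"]

ARCHETYPES = ("monotone_up", "monotone_down", "transient_peak", "switch")

# latent trajectory: gentle early rise + steep ripening-onset rise (days)
_C1, _S1 = 40.0, 12.0
_C2, _S2 = 70.0, 5.0


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def latent_stage(dev_day: np.ndarray) -> np.ndarray:
    """Latent developmental stage in [0, 1] as a function of development day."""
    d = np.asarray(dev_day, dtype=float)
    return 0.5 * _sigmoid((d - _C1) / _S1) + 0.5 * _sigmoid((d - _C2) / _S2)


@dataclass
class SyntheticTruth:
    seed: int
    latent: np.ndarray  # per condition, in [0, 1]
    archetype: list[str]  # per gene
    gene_params: dict[str, np.ndarray]
    baseline: np.ndarray
    vintage_shift: dict[str, float]  # days
    cultivar_lag: dict[str, float]  # days
    cultivar_offset: np.ndarray  # genes x cultivars, multiplicative (log scale 0 = none)
    vintage_offset: np.ndarray
    noise_cv: float
    stage_dependent_noise: bool
    # development-day interval where the planted (noise-free) transcriptome
    # changes fastest; computed from the mean profiles at generation time
    rapid_window_days: tuple[float, float] = (_C2 - 2 * _S2, _C2 + 2 * _S2)
    condition_days: np.ndarray | None = None  # development day per condition

    def rapid_window_for_series(self, shift: float) -> tuple[float, float]:
        lo, hi = self.rapid_window_days
        return (lo + shift, hi + shift)

    def series_shift(self, cultivar: str, vintage: str) -> float:
        return self.cultivar_lag[cultivar] + self.vintage_shift[vintage]


def _archetype_profile(name: str, params: np.ndarray, s: np.ndarray) -> np.ndarray:
    if name == "monotone_up":
        return s ** params[0]
    if name == "monotone_down":
        return (1.0 - s) ** params[0]
    if name == "transient_peak":
        mu, width = params
        return np.exp(-((s - mu) ** 2) / (2.0 * width**2))
    if name == "switch":
        tau, direction = params
        g = _sigmoid((s - tau) / 0.06)
        return g if direction > 0 else 1.0 - g
    raise ValueError(f"unknown archetype {name}")


def _lognormal_factor(rng: np.random.Generator, cv: np.ndarray, shape) -> np.ndarray:
    """Mean-1 multiplicative lognormal noise with the given CV."""
    sigma = np.sqrt(np.log1p(np.asarray(cv, dtype=float) ** 2))
    return np.exp(rng.normal(0.0, 1.0, size=shape) * sigma - sigma**2 / 2.0)


def generate_dataset(
    n_genes: int = 2000,
    n_cultivars: int = 2,
    n_vintages: int = 3,
    timepoint_range: tuple[int, int] = (10, 14),
    n_replicates: int = 3,
    noise_cv: float = 0.15,
    frac_noise_genes: float = 0.2,
    stage_dependent_noise: bool = False,
    cultivar_affected_frac: float = 0.15,
    vintage_affected_frac: float = 0.10,
    cultivar_offset_sd: float = 0.25,
    vintage_offset_sd: float = 0.20,
    affected_overlap: str = "independent",
    archetype_pool: tuple[str, ...] = ARCHETYPES,
    noise_gene_condition_cv: float = 0.5,
    seed: int = 0,
) -> tuple[ExpressionTensor, SyntheticTruth]:
    """Generate a replicate-level expression tensor plus its ground truth."""
    if not 0.0 <= frac_noise_genes <= 1.0:
        raise ValueError("frac_noise_genes must be in [0, 1]")
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    rng = np.random.default_rng(seed)

    cultivars = [f"CV{c + 1}" for c in range(n_cultivars)]
    vintages = [f"Y{v + 1}" for v in range(n_vintages)]
    cultivar_lag = {c: 6.0 * i for i, c in enumerate(cultivars)}
    vintage_shift = {v: float(rng.uniform(-10.0, 10.0)) for v in vintages}

    # series designs: weekly-ish sampling over the full development span
    meta: list[SampleMeta] = []
    dev_days: list[float] = []
    for c in cultivars:
        for v in vintages:
            n_t = int(rng.integers(timepoint_range[0], timepoint_range[1] + 1))
            gaps = rng.uniform(7.0, 10.0, size=n_t - 1)
            days = np.concatenate([[0.0], np.cumsum(gaps)])
            # stretch to cover the whole trajectory regardless of count
            days *= 105.0 / days[-1]
            shift = cultivar_lag[c] + vintage_shift[v]
            for t in range(n_t):
                doy = int(round(150 + days[t] + shift))
                meta.append(SampleMeta(
                    condition_id=f"{c}_{v}_T{t + 1:02d}",
                    cultivar=c, vintage=v, timepoint=t + 1,
                    doy=doy, daf=int(round(days[t])),
                ))
                dev_days.append(days[t])
    dev_days = np.asarray(dev_days)
    s = latent_stage(dev_days)
    n_cond = len(meta)

    # gene-level truth
    n_noise = int(round(frac_noise_genes * n_genes))
    bad = set(archetype_pool) - set(ARCHETYPES)
    if bad:
        raise ValueError(f"unknown archetypes {sorted(bad)}")
    archetype = (
        list(rng.choice(archetype_pool, size=n_genes - n_noise))
        + ["noise"] * n_noise
    )
    gene_ids = [f"G{i + 1:05d}" for i in range(n_genes)]
    baseline = rng.lognormal(mean=np.log(20.0), sigma=0.8, size=n_genes)
    params: dict[str, np.ndarray] = {}
    for i, a in enumerate(archetype):
        if a in ("monotone_up", "monotone_down"):
            params[gene_ids[i]] = np.asarray([rng.uniform(0.5, 2.0)])
        elif a == "transient_peak":
            params[gene_ids[i]] = np.asarray(
                [rng.uniform(0.2, 0.8), rng.uniform(0.08, 0.2)]
            )
        elif a == "switch":
            params[gene_ids[i]] = np.asarray(
                [rng.uniform(0.3, 0.7), rng.choice([-1.0, 1.0])]
            )
        else:
            params[gene_ids[i]] = np.asarray([])

    # genotype/vintage-affected genes carry a guaranteed mean-centered
    # log-scale contrast across levels (so every "affected" label is real)
    def _contrasts(rows: np.ndarray, n_levels: int, sd: float) -> np.ndarray:
        z = rng.normal(size=(rows.size, n_levels))
        z -= z.mean(axis=1, keepdims=True)
        norm = z.std(axis=1, keepdims=True)
        z /= np.where(norm > 0, norm, 1.0)
        eff = sd * rng.uniform(0.5, 1.5, size=(rows.size, 1))
        return z * eff

    cultivar_offset = np.zeros((n_genes, n_cultivars))
    vintage_offset = np.zeros((n_genes, n_vintages))
    traj = np.flatnonzero(np.asarray(archetype) != "noise")
    n_ca = int(round(cultivar_affected_frac * traj.size))
    n_va = int(round(vintage_affected_frac * traj.size))
    if affected_overlap == "nested":
        # the smaller affected set is a subset of the larger one, so genes
        # are either confound-free or confound-driven (possibly by both)
        big = rng.choice(traj, size=max(n_ca, n_va), replace=False)
        small = rng.choice(big, size=min(n_ca, n_va), replace=False)
        ca, va = (big, small) if n_ca >= n_va else (small, big)
    elif affected_overlap == "independent":
        ca = rng.choice(traj, size=n_ca, replace=False)
        va = rng.choice(traj, size=n_va, replace=False)
    else:
        raise ValueError(f"unknown affected_overlap {affected_overlap!r}")
    if n_ca:
        cultivar_offset[ca] = _contrasts(ca, n_cultivars, cultivar_offset_sd)
    if n_va:
        vintage_offset[va] = _contrasts(va, n_vintages, vintage_offset_sd)

    # condition x gene mean expression
    mean = np.empty((n_cond, n_genes))
    cidx = {c: i for i, c in enumerate(cultivars)}
    vidx = {v: i for i, v in enumerate(vintages)}
    for i, (g, a) in enumerate(zip(gene_ids, archetype)):
        if a == "noise":
            mean[:, i] = baseline[i] * _lognormal_factor(
                rng, noise_gene_condition_cv, n_cond
            )
        else:
            prof = 0.15 + 0.85 * _archetype_profile(a, params[g], s)
            mean[:, i] = baseline[i] * prof
    crow = np.asarray([cidx[m.cultivar] for m in meta])
    vrow = np.asarray([vidx[m.vintage] for m in meta])
    mean *= np.exp(cultivar_offset[:, crow].T + vintage_offset[:, vrow].T)

    # replicate noise
    if stage_dependent_noise:
        cv_cond = noise_cv * (1.0 + 1.5 * (2.0 * s - 1.0) ** 2)
    else:
        cv_cond = np.full(n_cond, noise_cv)
    factors = _lognormal_factor(
        rng, cv_cond[:, None, None], (n_cond, n_replicates, n_genes)
    )
    values = mean[:, None, :] * factors

    # normalize condition order to (cultivar, vintage, timepoint)
    order = sorted(
        range(n_cond), key=lambda j: (meta[j].cultivar, meta[j].vintage, meta[j].timepoint)
    )
    meta = [meta[j] for j in order]
    values = values[order]
    s = s[order]
    dev_days = dev_days[order]

    # rapid-transition window: where the planted noise-free transcriptome
    # moves fastest per day (norm of the standardized profile derivative)
    dgrid = np.linspace(0.0, 105.0, 500)
    sgrid = latent_stage(dgrid)
    prof_grid = np.stack([
        _archetype_profile(a, params[g], sgrid)
        for g, a in zip(gene_ids, archetype) if a != "noise"
    ])
    sdev = prof_grid.std(axis=1, keepdims=True)
    zgrid = (prof_grid - prof_grid.mean(axis=1, keepdims=True)) / np.where(
        sdev > 0, sdev, 1.0
    )
    speed = np.linalg.norm(np.diff(zgrid, axis=1), axis=0) / np.diff(dgrid)
    dmid = (dgrid[:-1] + dgrid[1:]) / 2.0
    peak = int(np.argmax(speed))
    thresh = 0.5 * speed[peak]
    lo = peak
    while lo > 0 and speed[lo - 1] >= thresh:
        lo -= 1
    hi = peak
    while hi < speed.size - 1 and speed[hi + 1] >= thresh:
        hi += 1
    rapid_window = (float(dmid[lo]), float(dmid[hi]))

    tensor = ExpressionTensor(values, gene_ids, meta, n_replicates)
    truth = SyntheticTruth(
        seed=seed, latent=s, archetype=archetype, gene_params=params,
        baseline=baseline, vintage_shift=vintage_shift, cultivar_lag=cultivar_lag,
        cultivar_offset=cultivar_offset, vintage_offset=vintage_offset,
        noise_cv=noise_cv, stage_dependent_noise=stage_dependent_noise,
        rapid_window_days=rapid_window, condition_days=dev_days,
    )
    return tensor, truth


def generate_reference_panel(
    truth: SyntheticTruth,
    n_cultivars: int = 10,
    n_stages: int = 4,
    n_replicates: int = 3,
    noise_cv: float = 0.15,
    seed: int = 1,
) -> ExpressionTensor:
    """A multi-cultivar, few-stage screening reference sharing the same genes.

    Samples the stored gene archetypes at ``n_stages`` latent stages for
    ``n_cultivars`` new cultivars in a single vintage.
    """
    rng = np.random.default_rng(seed)
    gene_ids = list(truth.gene_params.keys())
    n_genes = len(gene_ids)
    stages = np.linspace(0.12, 0.92, n_stages)
    noise_mask = np.asarray(truth.archetype) == "noise"
    prof = np.ones((n_stages, n_genes))
    for i, (g, a) in enumerate(zip(gene_ids, truth.archetype)):
        if a != "noise":
            prof[:, i] = 0.15 + 0.85 * _archetype_profile(
                a, truth.gene_params[g], stages
            )
    meta: list[SampleMeta] = []
    means = []
    for c in range(n_cultivars):
        cname = f"REF{c + 1:02d}"
        offs = rng.normal(0.0, 0.15, size=n_genes)
        block = truth.baseline[None, :] * prof
        if noise_mask.any():
            block = block.copy()
            block[:, noise_mask] = truth.baseline[noise_mask][None, :] * \
                _lognormal_factor(rng, 0.5, (n_stages, int(noise_mask.sum())))
        means.append(block * np.exp(offs)[None, :])
        for t in range(n_stages):
            meta.append(SampleMeta(
                condition_id=f"{cname}_T{t + 1}", cultivar=cname,
                vintage="Y1", timepoint=t + 1,
            ))
    mean = np.concatenate(means, axis=0)
    factors = _lognormal_factor(rng, noise_cv, (mean.shape[0], n_replicates, n_genes))
    values = mean[:, None, :] * factors
    return ExpressionTensor(values, gene_ids, meta, n_replicates)
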