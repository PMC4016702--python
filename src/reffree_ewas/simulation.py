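"""Synthetic EWAS data generator and simulation-study harness.

The generator emulates a methylation array measured on a heterogeneous
tissue (blood-like, k cell types).  For CpG j and sample i the linear-scale
mean is

    m_ji = μ_j + Δ_j·x_i + Σ_l M_jl (ω_il − base_l)

where x is the phenotype, Δ the *direct* (non-cell-mediated) effect, M the
cell-type methylation deviations (non-zero only at DMR rows), and ω_i the
sample's cell-mixture proportions, drawn from a Dirichlet whose mean tilts
with x at strength τ.  Biological noise is beta-distributed around m_ji
with row dispersions tuned to an average variance θ; microarray noise is
added on the logit scale as a q-factor structure plus correlated
uniqueness errors, and the observed value is the inverse-logit of the sum.

Four canonical scenarios cross ζ (direct-effect strength) × τ
(mixture-effect strength) over {0, 1}; ``run_scenario`` simulates many
datasets per scenario and reports RMSE and standard-error-calibration
metrics for the direct-effect estimator against the unadjusted analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, logit

from .dimension import est_dim_rmt
from .inference import BootstrapSpec, bootstrap_standard_errors
from .linear_core import (
    DesignMatrix,
    MethylationMatrix,
    estimate_direct_effects,
    fit_unadjusted,
    ols_standard_errors,
)

__all__ = [
    "SimScenario",
    "SimTruth",
    "ScenarioReport",
    "scenario_preset",
    "gen_effects",
    "gen_cell_structure",
    "gen_mixtures",
    "make_truth",
    "simulate_dataset",
    "run_scenario",
]

# canonical effect counts at m = 1000: scaled proportionally for other m
_NEG_PER_1000 = 30
_POS_PER_1000 = 23


@dataclass
class SimScenario:
    """All generative parameters of one simulation condition.

    Defaults are the canonical study conditions: m=1000 CpGs, n=250
    samples, k=4 cell types, q=2 array factors, 250 DMR rows, uniqueness
    SD 0.25 on the logit scale.  ζ and τ switch the direct and
    mixture-mediated effects on and off.
    """

    m: int = 1000
    n: int = 250
    k: int = 4
    q: int = 2
    zeta: float = 1.0
    tau: float = 1.0
    dmr_rows: int = 250
    theta: float = 1e-3
    dirichlet_base: tuple[float, ...] = (0.55, 0.25, 0.12, 0.08)
    dirichlet_concentration: float = 40.0
    uniqueness_sd: float = 0.25
    uniqueness_rho: float = 0.3
    factor_scale: float = 0.1
    intercept_beta: tuple[float, float] = (1.5, 15.0)
    effect_scale: float = 0.05
    dmr_deviation_halfwidth: float = 0.4
    mean_clamp: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        base = np.asarray(self.dirichlet_base, dtype=float)
        if base.size != self.k:
            raise ValueError("dirichlet_base length must equal k")
        if not np.isclose(base.sum(), 1.0) or (base <= 0).any():
            raise ValueError("dirichlet_base must be positive and sum to 1")
        if self.zeta < 0 or self.tau < 0:
            raise ValueError("zeta and tau must be nonnegative")
        if self.dmr_rows > self.m:
            raise ValueError("dmr_rows cannot exceed m")

    @property
    def base(self) -> np.ndarray:
        return np.asarray(self.dirichlet_base, dtype=float)

    @property
    def mixture_contrast(self) -> np.ndarray:
        """Fixed unit vector along which the phenotype tilts log-proportions."""
        v = np.array([1.0 if l % 2 == 0 else -1.0 for l in range(self.k)])
        return v / np.linalg.norm(v)


@dataclass
class SimTruth:
    """Realised truth of one simulated dataset."""

    delta: np.ndarray  # m×2: column 0 intercept μ, column 1 direct slope Δ
    cell_means_dev: np.ndarray  # m×k, zero outside DMR rows
    omega: np.ndarray  # n×k mixture proportions
    x: np.ndarray  # n phenotype values
    effect_labels: np.ndarray  # m, in {"negative","positive","null"}

    @property
    def mu(self) -> np.ndarray:
        return self.delta[:, 0]

    @property
    def direct_slope(self) -> np.ndarray:
        return self.delta[:, 1]


@dataclass
class ScenarioReport:
    rmse_direct_vs_truth: float  # Δ̂ vs Δ
    rmse_unadjusted_vs_truth: float  # B̃ slope vs Δ
    rmse_total_vs_unadjusted: float  # B̃ slope vs total effect
    se_inflation_direct: float  # median over CpGs of median boot SE / sim SD
    se_inflation_unadjusted: float  # same ratio, asymptotic SEs for B̃
    n_datasets: int
    n_bootstrap: int
    dims_estimated: list[int] = field(default_factory=list)


def scenario_preset(number: int, **overrides) -> SimScenario:
    """Scenarios 1–4: (ζ, τ) = (1,1), (1,0), (0,1), (0,0)."""
    table = {1: (1.0, 1.0), 2: (1.0, 0.0), 3: (0.0, 1.0), 4: (0.0, 0.0)}
    if number not in table:
        raise ValueError("scenario number must be 1–4")
    zeta, tau = table[number]
    return SimScenario(zeta=zeta, tau=tau, **overrides)


def _effect_counts(m: int) -> tuple[int, int]:
    if m == 1000:
        return _NEG_PER_1000, _POS_PER_1000
    return round(_NEG_PER_1000 * m / 1000), round(_POS_PER_1000 * m / 1000)


def gen_effects(
    scenario: SimScenario, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw intercepts μ and direct-effect slopes Δ with sign labels.

    Intercepts come from a bimodal (low/high methylation) beta mixture.
    Exactly 30 negative / 23 positive / 947 null slopes at m=1000
    (proportional otherwise); non-null slopes land preferentially on
    mid-range CpGs (weight ∝ μ(1−μ)) and their signs associate inversely
    with μ — highly methylated CpGs tend to lose methylation.  Slope
    magnitudes are half-normal at ``effect_scale``, multiplied by ζ.
    """
    m = scenario.m
    n_neg, n_pos = _effect_counts(m)
    if n_neg + n_pos > m:
        raise ValueError("non-null effect counts exceed m")

    # strongly bimodal intercepts, as on real arrays (modes near 0 and 1)
    a, b = scenario.intercept_beta
    low = rng.random(m) < 0.5
    mu = np.where(low, rng.beta(a, b, size=m), rng.beta(b, a, size=m))

    w = mu * (1.0 - mu)
    nonnull = rng.choice(m, size=n_neg + n_pos, replace=False, p=w / w.sum())
    # negative slopes drawn preferentially at high μ
    w_neg = mu[nonnull]
    neg = rng.choice(
        nonnull, size=n_neg, replace=False, p=w_neg / w_neg.sum()
    )
    pos = np.setdiff1d(nonnull, neg)

    slope = np.zeros(m)
    mag = np.abs(rng.normal(0.0, scenario.effect_scale, size=m))
    slope[neg] = -mag[neg]
    slope[pos] = mag[pos]
    slope *= scenario.zeta

    labels = np.full(m, "null", dtype=object)
    if scenario.zeta > 0:
        labels[neg] = "negative"
        labels[pos] = "positive"
    return mu, slope, np.asarray(labels)


def gen_cell_structure(scenario: SimScenario, rng: np.random.Generator) -> np.ndarray:
    """Cell-type methylation deviations M: m×k, non-zero on DMR rows only.

    DMR entries are Beta(2,2) draws rescaled to ±halfwidth around zero,
    i.e. symmetric deviations of the cell-type mean from the bulk mean.
    """
    M = np.zeros((scenario.m, scenario.k))
    r = scenario.dmr_rows
    if r > 0:
        M[:r] = (rng.beta(2.0, 2.0, size=(r, scenario.k)) - 0.5) * (
            2.0 * scenario.dmr_deviation_halfwidth
        )
    return M


def gen_mixtures(
    scenario: SimScenario, x: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Sample-wise cell proportions Ω ~ Dirichlet(c·π(x)).

    The Dirichlet mean π_i tilts the baseline composition along a fixed
    unit contrast in log space, π_i = softmax(log base + τ·x̃_i·v), with
    x̃ the centered phenotype; concentration c controls sample-to-sample
    variability (c = 40 gives blood-plausible spreads).
    """
    xt = np.asarray(x, dtype=float) - 0.5
    v = scenario.mixture_contrast
    logits = np.log(scenario.base)[None, :] + scenario.tau * xt[:, None] * v[None, :]
    logits -= logits.max(axis=1, keepdims=True)
    pi = np.exp(logits)
    pi /= pi.sum(axis=1, keepdims=True)
    alphas = scenario.dirichlet_concentration * pi
    omega = np.vstack([rng.dirichlet(a) for a in alphas])
    return omega


def _dirichlet_mean(scenario: SimScenario, x: np.ndarray) -> np.ndarray:
    xt = np.asarray(x, dtype=float) - 0.5
    v = scenario.mixture_contrast
    logits = np.log(scenario.base)[None, :] + scenario.tau * xt[:, None] * v[None, :]
    logits -= logits.max(axis=1, keepdims=True)
    pi = np.exp(logits)
    return pi / pi.sum(axis=1, keepdims=True)


def total_effect_slope(scenario: SimScenario, truth: SimTruth) -> np.ndarray:
    """Analytic total (direct + mixture-mediated) slope of the mean on x.

    dE[ω_l]/dx = τ·π_l(v_l − πᵀv) from the softmax mean; the mediated part
    is M · dE[ω]/dx averaged over the dataset's samples, added to Δ.
    """
    pi = _dirichlet_mean(scenario, truth.x)
    v = scenario.mixture_contrast
    dpi = scenario.tau * pi * (v[None, :] - (pi @ v)[:, None])
    return truth.direct_slope + truth.cell_means_dev @ dpi.mean(axis=0)


def make_truth(
    scenario: SimScenario,
    rng: np.random.Generator,
    mu: np.ndarray | None = None,
    slope: np.ndarray | None = None,
    labels: np.ndarray | None = None,
    cell_means_dev: np.ndarray | None = None,
) -> SimTruth:
    """Realise one dataset's truth; fixed components may be passed in."""
    if mu is None or slope is None or labels is None:
        mu, slope, labels = gen_effects(scenario, rng)
    if cell_means_dev is None:
        cell_means_dev = gen_cell_structure(scenario, rng)
    x = rng.random(scenario.n)
    omega = gen_mixtures(scenario, x, rng)
    return SimTruth(
        delta=np.column_stack([mu, slope]),
        cell_means_dev=cell_means_dev,
        omega=omega,
        x=x,
        effect_labels=labels,
    )


def simulate_dataset(
    scenario: SimScenario, truth: SimTruth, rng: np.random.Generator
) -> MethylationMatrix:
    """Observed beta values for one dataset.

    Linear means are clamped to [ε, 1−ε]; beta-distributed biological
    noise uses row dispersions tuned so the average per-entry variance is
    θ; microarray error (q-factor + correlated uniqueness, logit scale)
    is added and the inverse logit taken.
    """
    m, n, k, q = scenario.m, scenario.n, scenario.k, scenario.q
    eps = scenario.mean_clamp
    means = (
        truth.mu[:, None]
        + np.outer(truth.direct_slope, truth.x)
        + truth.cell_means_dev @ (truth.omega - scenario.base[None, :]).T
    )
    clamped = np.clip(means, eps, 1.0 - eps)
    frac_clamped = np.mean(clamped != means)
    if frac_clamped > 0.05:
        raise ValueError(
            f"{frac_clamped:.1%} of linear means hit the [{eps}, {1 - eps}] "
            "boundary; generator parameters are implausible"
        )

    # row dispersion φ_j so that mean_i var(b_ji) = θ
    avg_mv = (clamped * (1.0 - clamped)).mean(axis=1)
    phi = np.maximum(avg_mv / scenario.theta - 1.0, 1.0)
    a = clamped * phi[:, None]
    b = (1.0 - clamped) * phi[:, None]
    bio = rng.beta(a, b)
    bio = np.clip(bio, 1e-12, 1.0 - 1e-12)

    lam = rng.normal(size=(m, q))
    pfac = rng.normal(size=(n, q))
    shared = rng.normal(size=n)
    unique = rng.normal(size=(m, n))
    rho = scenario.uniqueness_rho
    u = scenario.uniqueness_sd * (
        np.sqrt(rho) * shared[None, :] + np.sqrt(1.0 - rho) * unique
    )
    e = scenario.factor_scale * (lam @ pfac.T) + u

    y = expit(logit(bio) + e)
    return MethylationMatrix(
        values=y,
        cpg_ids=[f"cpg{j}" for j in range(m)],
        sample_ids=[f"s{i}" for i in range(n)],
    )


def design_for(truth: SimTruth) -> DesignMatrix:
    """Intercept + phenotype design for a simulated dataset."""
    return DesignMatrix(
        values=np.column_stack([np.ones(truth.x.size), truth.x]),
        column_names=["intercept", "x"],
    )


def run_scenario(
    scenario: SimScenario,
    n_datasets: int = 100,
    n_bootstrap: int = 0,
    d: int | None = None,
) -> ScenarioReport:
    """Simulate many datasets and score the estimator against the truth.

    Per dataset: draw phenotype/mixtures/noise, estimate the latent
    dimension by RMT on [B̃ | Ẽ] (unless ``d`` is fixed), compute Δ̂ and
    B̃, and optionally bootstrap SEs for Δ̂.  RMSEs pool squared errors
    over CpGs and datasets; SE inflation is the median over CpGs of
    (median-over-datasets SE) / (SD-over-datasets of the estimate), with
    asymptotic linear-model SEs for the unadjusted column.
    """
    if n_datasets < 2:
        raise ValueError("need at least 2 datasets")
    ss = np.random.SeedSequence(scenario.seed)
    fixed_rng = np.random.default_rng(ss.spawn(1)[0])
    mu, slope, labels = gen_effects(scenario, fixed_rng)
    M = gen_cell_structure(scenario, fixed_rng)

    m = scenario.m
    child_seeds = ss.spawn(n_datasets)
    direct_slopes = np.empty((n_datasets, m))
    unadj_slopes = np.empty((n_datasets, m))
    sq_dir = np.empty((n_datasets, m))
    sq_unadj = np.empty((n_datasets, m))
    sq_total = np.empty((n_datasets, m))
    se_dir = np.full((n_datasets, m), np.nan)
    se_unadj = np.empty((n_datasets, m))
    dims: list[int] = []

    for t, child in enumerate(child_seeds):
        rng = np.random.default_rng(child)
        truth = make_truth(
            scenario, rng, mu=mu, slope=slope, labels=labels, cell_means_dev=M
        )
        Y = simulate_dataset(scenario, truth, rng)
        X = design_for(truth)
        if d is None:
            fit0 = fit_unadjusted(Y, X)
            Z = np.hstack([fit0.coefficients, fit0.residuals])
            d_t = est_dim_rmt(Z[fit0.complete_rows]).d
        else:
            d_t = d
        dims.append(d_t)
        fit, _, est = estimate_direct_effects(Y, X, d_t)

        dhat = est.direct_effects[:, 1]
        bhat = est.unadjusted[:, 1]
        total = total_effect_slope(scenario, truth)
        direct_slopes[t] = dhat
        unadj_slopes[t] = bhat
        sq_dir[t] = (dhat - truth.direct_slope) ** 2
        sq_unadj[t] = (bhat - truth.direct_slope) ** 2
        sq_total[t] = (bhat - total) ** 2
        se_unadj[t] = ols_standard_errors(fit)[:, 1]

        if n_bootstrap >= 2:
            boot_seed = int(child.generate_state(1, dtype=np.uint32)[0] >> 1)
            spec = BootstrapSpec(replicates=n_bootstrap, seed=boot_seed)
            res = bootstrap_standard_errors(
                Y, X, d_t, spec, compute_qvalues=False
            )
            se_dir[t] = res.se_direct[:, 1]

    def infl(se: np.ndarray, estimates: np.ndarray) -> float:
        med_se = np.nanmedian(se, axis=0)
        sim_sd = estimates.std(axis=0, ddof=1)
        return float(np.median(med_se / sim_sd))

    return ScenarioReport(
        rmse_direct_vs_truth=float(np.sqrt(sq_dir.mean())),
        rmse_unadjusted_vs_truth=float(np.sqrt(sq_unadj.mean())),
        rmse_total_vs_unadjusted=float(np.sqrt(sq_total.mean())),
        se_inflation_direct=(
            infl(se_dir, direct_slopes) if n_bootstrap >= 2 else float("nan")
        ),
        se_inflation_unadjusted=infl(se_unadj, unadj_slopes),
        n_datasets=n_datasets,
        n_bootstrap=n_bootstrap,
        dims_estimated=dims,
    )
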