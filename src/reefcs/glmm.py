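"""Random-intercept count models of fish abundance on hard-coral cover.

Fits Poisson, negative-binomial (NB2: variance mu + mu^2/theta), and their
zero-inflated variants with a year-level Gaussian random intercept:

    log mu_it = beta0 + beta1 * coral_it + u_t,   u_t ~ N(0, sigma^2)

with an intercept-only logit for the structural-zero probability
(pi = expit(gamma0)) in the zero-inflated variants. The marginal likelihood
integrates the year intercepts out by adaptive Gauss-Hermite quadrature
(mode + curvature per year group, default 15 nodes); estimation is
bounded quasi-Newton (L-BFGS-B) from a moment-based start plus random
restarts, Wald inference for the coral slope from a finite-difference
Hessian. AIC-based selection and the family -> species screening rules
(slope significance, >1% community-abundance contribution, cumulative 90%
within-family share) are layered on top.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, gammaln, logsumexp
from scipy.stats import norm

from .synth import CELL_COLUMNS

DISTRIBUTIONS = ("poisson", "nb", "zip", "zinb")

_SIGMA_MAX = 5.0
_LOG_THETA_BOUNDS = (-7.0, 7.0)
_GAMMA0_BOUNDS = (-30.0, 10.0)
_SIGMA_BOUNDARY = 1e-4


@dataclass
class CountModelFit:
    """Fitted random-intercept count model (fixed effects on the log link)."""

    distribution: str
    beta0: float
    beta1: float
    se_beta0: float
    se_beta1: float
    sigma2: float                 # random-intercept variance
    se_sigma2: float              # delta-method SD of the variance estimate
    theta: float | None           # NB dispersion (None for Poisson family)
    gamma0: float | None          # zero-inflation logit intercept
    loglik: float
    n_params: int
    aic: float
    wald_z: float
    wald_p: float
    converged: bool
    quad_nodes: int
    n_obs: int
    n_groups: int
    boundary_sigma: bool = False
    message: str = ""

    @property
    def sigma(self) -> float:
        return math.sqrt(self.sigma2)

    @property
    def pi(self) -> float | None:
        return None if self.gamma0 is None else float(expit(self.gamma0))

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in (
            "distribution", "beta0", "beta1", "se_beta0", "se_beta1", "sigma2",
            "se_sigma2", "theta", "gamma0", "loglik", "n_params", "aic",
            "wald_z", "wald_p", "converged", "quad_nodes", "n_obs", "n_groups",
            "boundary_sigma", "message")}
        d["pi"] = self.pi
        return d


# ---------------------------------------------------------------------------
# Observation-level log-likelihood and its derivatives in u
# ---------------------------------------------------------------------------

def _count_loglik_and_grad(y, eta, dist, theta, pi):
    """Per-observation log-likelihood and d/du (u enters eta additively)."""
    mu = np.exp(eta)
    if dist in ("poisson", "zip"):
        ll_count = y * eta - mu - gammaln(y + 1)
        g_count = y - mu
        log_p0 = -mu
        g_p0 = -mu  # d log p0 / du
    else:
        ll_count = (gammaln(y + theta) - gammaln(theta) - gammaln(y + 1)
                    + theta * np.log(theta) + y * eta
                    - (y + theta) * np.log(theta + mu))
        g_count = y - (theta + y) * mu / (theta + mu)
        log_p0 = theta * (np.log(theta) - np.log(theta + mu))
        g_p0 = -theta * mu / (theta + mu)
    if dist in ("poisson", "nb"):
        return ll_count, g_count
    # zero-inflated mixture
    is0 = y == 0
    ll = np.where(is0, 0.0, np.log1p(-pi) + ll_count)
    g = np.where(is0, 0.0, g_count)
    if is0.any():
        p0 = np.exp(log_p0[is0])
        mix = pi + (1.0 - pi) * p0
        ll_zero = np.log(np.maximum(mix, 1e-300))
        g_zero = (1.0 - pi) * p0 * g_p0[is0] / np.maximum(mix, 1e-300)
        ll = ll.copy(); g = g.copy()
        ll[is0] = ll_zero
        g[is0] = g_zero
    return ll, g


class _MarginalLoglik:
    """Adaptive Gauss-Hermite marginal log-likelihood over year groups.

    Keeps the last group modes as warm starts for the inner Newton search
    across successive optimizer evaluations.
    """

    def __init__(self, y, coral, group_idx, n_groups, dist, quad_nodes):
        self.y = np.asarray(y, dtype=float)
        self.coral = np.asarray(coral, dtype=float)
        self.group_idx = np.asarray(group_idx)
        self.n_groups = int(n_groups)
        self.dist = dist
        self.nodes, self.weights = np.polynomial.hermite.hermgauss(quad_nodes)
        self.log_weights = np.log(self.weights)
        self.u_warm = np.zeros(self.n_groups)

    def _group_obs_loglik(self, u_by_group, b0, b1, theta, pi):
        eta = b0 + b1 * self.coral + u_by_group[self.group_idx]
        ll, g = _count_loglik_and_grad(self.y, eta, self.dist, theta, pi)
        ll_g = np.bincount(self.group_idx, weights=ll, minlength=self.n_groups)
        g_g = np.bincount(self.group_idx, weights=g, minlength=self.n_groups)
        return ll_g, g_g

    def _find_modes(self, b0, b1, sigma, theta, pi):
        """Vectorised Newton search for the per-group posterior modes."""
        u = self.u_warm.copy()
        inv_s2 = 1.0 / (sigma * sigma)
        h = 1e-4
        for _ in range(40):
            _, g = self._group_obs_loglik(u, b0, b1, theta, pi)
            grad = g - u * inv_s2
            if np.max(np.abs(grad)) < 1e-9:
                break
            _, g_hi = self._group_obs_loglik(u + h, b0, b1, theta, pi)
            _, g_lo = self._group_obs_loglik(u - h, b0, b1, theta, pi)
            curv = (g_hi - g_lo) / (2 * h) - inv_s2
            curv = np.minimum(curv, -1e-8)
            step = np.clip(-grad / curv, -2.0, 2.0)
            u = u + step
            if np.max(np.abs(step)) < 1e-10:
                break
        _, g_hi = self._group_obs_loglik(u + h, b0, b1, theta, pi)
        _, g_lo = self._group_obs_loglik(u - h, b0, b1, theta, pi)
        curv = (g_hi - g_lo) / (2 * h) - inv_s2
        curv = np.minimum(curv, -1e-8)
        self.u_warm = u
        return u, curv

    def __call__(self, b0, b1, sigma, theta=None, pi=None) -> float:
        if sigma < _SIGMA_BOUNDARY:
            ll_g, _ = self._group_obs_loglik(np.zeros(self.n_groups), b0, b1, theta, pi)
            return float(ll_g.sum())
        u_hat, curv = self._find_modes(b0, b1, sigma, theta, pi)
        h_scale = 1.0 / np.sqrt(-curv)
        # integrand g(u) = sum_i ll_i(u) + log phi(u; 0, sigma^2)
        K = len(self.nodes)
        pts = u_hat[:, None] + math.sqrt(2.0) * h_scale[:, None] * self.nodes[None, :]
        vals = np.empty((self.n_groups, K))
        for k in range(K):
            ll_g, _ = self._group_obs_loglik(pts[:, k], b0, b1, theta, pi)
            vals[:, k] = ll_g
        vals += norm.logpdf(pts, scale=sigma)
        log_int = logsumexp(
            self.log_weights[None, :] + self.nodes[None, :] ** 2 + vals, axis=1)
        log_int += 0.5 * math.log(2.0) + np.log(h_scale)
        return float(log_int.sum())


def _unpack(params, dist, fixed_sigma):
    b0, b1 = params[0], params[1]
    i = 2
    if fixed_sigma is None:
        sigma = params[i]; i += 1
    else:
        sigma = fixed_sigma
    theta = None
    pi = None
    if dist in ("nb", "zinb"):
        theta = math.exp(params[i]); i += 1
    gamma0 = None
    if dist in ("zip", "zinb"):
        gamma0 = params[i]; i += 1
        pi = float(expit(gamma0))
    return b0, b1, sigma, theta, pi, gamma0


def marginal_loglik(
    counts, coral, year,
    distribution: str,
    beta0: float, beta1: float, sigma: float,
    theta: float | None = None, gamma0: float | None = None,
    quad_nodes: int = 15,
) -> float:
    """Marginal log-likelihood at explicit parameter values.

    Exposed so that limiting cases (sigma = 0 equals a fixed-effects-only
    fit; zero inflation driven to gamma0 -> -inf recovers the plain count
    model) can be checked directly.
    """
    y, x, gidx, n_groups = _prepare(counts, coral, year)
    f = _MarginalLoglik(y, x, gidx, n_groups, distribution, quad_nodes)
    pi = None if gamma0 is None else float(expit(gamma0))
    return f(beta0, beta1, sigma, theta, pi)


def _prepare(counts, coral, year):
    y = np.asarray(counts, dtype=float)
    x = np.asarray(coral, dtype=float)
    yr = np.asarray(year)
    if not (len(y) == len(x) == len(yr)):
        raise ValueError("counts, coral and year must have equal length")
    if np.any(y < 0) or np.any(y != np.floor(y)):
        raise ValueError("counts must be non-negative integers")
    if np.any((x < 0) | (x > 100)):
        raise ValueError("coral cover must be within [0, 100]")
    levels, gidx = np.unique(yr, return_inverse=True)
    if len(levels) < 2:
        raise ValueError("need >= 2 year levels for a random intercept")
    return y, x, gidx, len(levels)


def fit_count_glmm(
    counts, coral, year,
    distribution: str = "nb",
    quad_nodes: int = 15,
    n_restarts: int = 5,
    seed: int | np.random.Generator | None = None,
    fixed_sigma: float | None = None,
) -> CountModelFit:
    """Maximum-likelihood fit of a random-intercept count model.

    ``fixed_sigma`` pins the random-intercept SD (0 gives the
    fixed-effects-only model on the same likelihood). Non-convergence is
    reported in the flag, never raised; a sigma estimate at the zero
    boundary is reported with ``boundary_sigma`` set.
    """
    if distribution not in DISTRIBUTIONS:
        raise ValueError(f"distribution must be one of {DISTRIBUTIONS}")
    y, x, gidx, n_groups = _prepare(counts, coral, year)
    if np.all(y == 0):
        raise ValueError("response is all zeros: no information to fit")
    if np.ptp(x) == 0:
        raise ValueError("coral cover is constant: slope unidentifiable")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    f = _MarginalLoglik(y, x, gidx, n_groups, distribution, quad_nodes)

    # moment-based start
    b1_0, b0_0 = np.polyfit(x, np.log(y + 0.5), 1)
    start = [b0_0, b1_0]
    bounds: list[tuple] = [(None, None), (None, None)]
    if fixed_sigma is None:
        start.append(0.3)
        bounds.append((0.0, _SIGMA_MAX))
    if distribution in ("nb", "zinb"):
        start.append(0.0)  # log theta
        bounds.append(_LOG_THETA_BOUNDS)
    if distribution in ("zip", "zinb"):
        frac0 = float(np.mean(y == 0))
        start.append(float(np.log(max(frac0, 0.05) / (1 - max(frac0, 0.05)))) - 1.0)
        bounds.append(_GAMMA0_BOUNDS)
    start = np.array(start, dtype=float)

    def neg_loglik(p):
        b0, b1, sigma, theta, pi, _ = _unpack(p, distribution, fixed_sigma)
        try:
            return -f(b0, b1, sigma, theta, pi)
        except FloatingPointError:
            return 1e12

    best = None
    for r in range(max(1, n_restarts)):
        p0 = start if r == 0 else start + rng.normal(0, 0.3, size=len(start))
        p0 = np.clip(p0, [b[0] if b[0] is not None else -np.inf for b in bounds],
                     [b[1] if b[1] is not None else np.inf for b in bounds])
        f.u_warm = np.zeros(n_groups)
        res = minimize(neg_loglik, p0, method="L-BFGS-B", bounds=bounds,
                       options={"maxiter": 300, "ftol": 1e-10})
        agrees = best is not None and res.fun > best.fun - 1e-9 \
            and res.fun < best.fun + 1e-4
        if best is None or res.fun < best.fun - 1e-9:
            best = res
        # stop once two starts agree on the optimum and it converged
        if r >= 1 and agrees and best.success:
            break
    res = best
    b0, b1, sigma, theta, pi, gamma0 = _unpack(res.x, distribution, fixed_sigma)
    loglik = -float(res.fun)

    n_params = 3 if fixed_sigma is None else 2
    if distribution in ("nb", "zinb"):
        n_params += 1
    if distribution in ("zip", "zinb"):
        n_params += 1

    boundary = bool(fixed_sigma is None and sigma < _SIGMA_BOUNDARY)

    names = ["beta0", "beta1"]
    if fixed_sigma is None:
        names.append("sigma")
    if distribution in ("nb", "zinb"):
        names.append("log_theta")
    if distribution in ("zip", "zinb"):
        names.append("gamma0")

    # Wald covariance from a finite-difference Hessian; directions that are
    # pinned at a bound (sigma at 0, log-theta at its cap) or flat (gamma0
    # driven to a negligible structural-zero probability) are dropped
    free_idx = []
    for i, name in enumerate(names):
        lo, hi = bounds[i]
        if name == "sigma" and boundary:
            continue
        if name == "gamma0" and res.x[i] < -10.0:
            continue
        if lo is not None and res.x[i] < lo + 1e-6:
            continue
        if hi is not None and res.x[i] > hi - 1e-6:
            continue
        free_idx.append(i)
    H = _num_hessian(neg_loglik, res.x, free_idx)
    se = np.full(len(res.x), np.nan)
    try:
        cov = np.linalg.inv(H)
        diag = np.diag(cov)
        if np.any(diag < 0):
            raise np.linalg.LinAlgError("negative variance")
        se[free_idx] = np.sqrt(diag)
        se_ok = True
    except np.linalg.LinAlgError:
        se_ok = False

    se_b0 = float(se[0]) if se_ok else float("nan")
    se_b1 = float(se[1]) if se_ok else float("nan")
    if fixed_sigma is None and not boundary and se_ok:
        se_sigma2 = float(2 * sigma * se[2])  # delta method var = sigma^2
    else:
        se_sigma2 = float("nan")

    wald_z = b1 / se_b1 if se_ok and se_b1 > 0 else float("nan")
    wald_p = 2 * norm.sf(abs(wald_z)) if np.isfinite(wald_z) else float("nan")

    return CountModelFit(
        distribution=distribution, beta0=float(b0), beta1=float(b1),
        se_beta0=se_b0, se_beta1=se_b1, sigma2=float(sigma ** 2),
        se_sigma2=se_sigma2, theta=None if theta is None else float(theta),
        gamma0=None if gamma0 is None else float(gamma0),
        loglik=loglik, n_params=n_params, aic=2 * n_params - 2 * loglik,
        wald_z=float(wald_z), wald_p=float(wald_p),
        converged=bool(res.success and se_ok), quad_nodes=quad_nodes,
        n_obs=len(y), n_groups=n_groups, boundary_sigma=boundary,
        message=str(res.message),
    )


def _num_hessian(fn, x, free_idx, h=1e-4):
    """Central-difference Hessian of ``fn`` restricted to ``free_idx``."""
    m = len(free_idx)
    H = np.empty((m, m))
    f0 = fn(x)
    for a in range(m):
        ia = free_idx[a]
        for b in range(a, m):
            ib = free_idx[b]
            if a == b:
                xp = x.copy(); xp[ia] += h
                xm = x.copy(); xm[ia] -= h
                H[a, a] = (fn(xp) - 2 * f0 + fn(xm)) / h ** 2
            else:
                xpp = x.copy(); xpp[ia] += h; xpp[ib] += h
                xpm = x.copy(); xpm[ia] += h; xpm[ib] -= h
                xmp = x.copy(); xmp[ia] -= h; xmp[ib] += h
                xmm = x.copy(); xmm[ia] -= h; xmm[ib] -= h
                H[a, b] = H[b, a] = (fn(xpp) - fn(xpm) - fn(xmp) + fn(xmm)) / (4 * h ** 2)
    return H


# ---------------------------------------------------------------------------
# Model selection
# ---------------------------------------------------------------------------

def aic_select(
    counts, coral, year,
    distributions=("poisson", "nb"),
    quad_nodes: int = 15,
    n_restarts: int = 5,
    seed: int | np.random.Generator | None = None,
) -> CountModelFit:
    """Fit the candidate distributions and return the converged fit with
    minimal AIC; exact ties go to the model with fewer parameters."""
    if len(distributions) < 2:
        raise ValueError("need >= 2 candidate distributions")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    fits = []
    for dist in distributions:
        fits.append(fit_count_glmm(counts, coral, year, dist,
                                   quad_nodes=quad_nodes,
                                   n_restarts=n_restarts, seed=rng))
    converged = [ft for ft in fits if ft.converged]
    if not converged:
        raise RuntimeError("no candidate model converged")
    converged.sort(key=lambda ft: (round(ft.aic, 9), ft.n_params))
    return converged[0]


# ---------------------------------------------------------------------------
# Community-level models and family/species screening
# ---------------------------------------------------------------------------

def _cell_responses(fish: pd.DataFrame, benthic: pd.DataFrame) -> pd.DataFrame:
    """One row per sampled transect-year (the benthic table defines the
    roster): total abundance, species richness, hard-coral cover."""
    cells = benthic[CELL_COLUMNS + ["hard_coral"]].copy()
    agg = fish.groupby(CELL_COLUMNS).agg(
        abundance=("count", "sum"), richness=("species", "nunique")).reset_index()
    out = cells.merge(agg, on=CELL_COLUMNS, how="left")
    out[["abundance", "richness"]] = out[["abundance", "richness"]].fillna(0).astype(int)
    return out


def community_models(
    fish: pd.DataFrame,
    benthic: pd.DataFrame,
    quad_nodes: int = 15,
    n_restarts: int = 5,
    seed: int | np.random.Generator | None = None,
) -> dict[str, CountModelFit]:
    """Total abundance and species richness per transect-year regressed on
    hard-coral cover (year random intercept), Poisson vs NB by AIC."""
    data = _cell_responses(fish, benthic)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = {}
    for response in ("abundance", "richness"):
        out[response] = aic_select(
            data[response], data["hard_coral"], data["year"],
            distributions=("poisson", "nb"), quad_nodes=quad_nodes,
            n_restarts=n_restarts, seed=rng)
    return out


@dataclass
class FamilyScreen:
    family: str
    contribution_pct: float
    fit: CountModelFit | None
    significant: bool
    selected: bool               # significant AND contribution > threshold
    error: str = ""


@dataclass
class SpeciesScreen:
    species: str
    family: str
    family_share_pct: float
    fit: CountModelFit | None
    significant: bool
    error: str = ""


@dataclass
class ScreeningResult:
    alpha: float
    contribution_threshold_pct: float
    cumulative_share_pct: float
    families: list[FamilyScreen] = field(default_factory=list)
    species: list[SpeciesScreen] = field(default_factory=list)

    @property
    def significant_families(self) -> list[str]:
        return [fs.family for fs in self.families if fs.significant]

    @property
    def selected_families(self) -> list[str]:
        return [fs.family for fs in self.families if fs.selected]

    def family_table(self) -> pd.DataFrame:
        rows = []
        for fs in self.families:
            ft = fs.fit
            rows.append({
                "family": fs.family, "contribution_pct": fs.contribution_pct,
                "distribution": ft.distribution if ft else None,
                "beta1": ft.beta1 if ft else np.nan,
                "se_beta1": ft.se_beta1 if ft else np.nan,
                "wald_p": ft.wald_p if ft else np.nan,
                "significant": fs.significant, "selected": fs.selected,
                "error": fs.error,
            })
        return pd.DataFrame(rows)

    def species_table(self) -> pd.DataFrame:
        rows = []
        for ss in self.species:
            ft = ss.fit
            rows.append({
                "species": ss.species, "family": ss.family,
                "family_share_pct": ss.family_share_pct,
                "distribution": ft.distribution if ft else None,
                "beta1": ft.beta1 if ft else np.nan,
                "se_beta1": ft.se_beta1 if ft else np.nan,
                "wald_p": ft.wald_p if ft else np.nan,
                "significant": ss.significant, "error": ss.error,
            })
        return pd.DataFrame(rows)


def screen_families(
    fish: pd.DataFrame,
    benthic: pd.DataFrame,
    traits: pd.DataFrame,
    alpha: float = 0.05,
    contribution_threshold_pct: float = 1.0,
    cumulative_share_pct: float = 90.0,
    distributions=("zip", "zinb"),
    quad_nodes: int = 15,
    n_restarts: int = 5,
    seed: int | np.random.Generator | None = None,
) -> ScreeningResult:
    """Family-level zero-inflated fits with the two screening rules.

    Every family is fitted (zip vs zinb by AIC) and its coral slope tested
    at ``alpha``. Families that are significant AND contribute more than
    ``contribution_threshold_pct`` of total community abundance get
    species-level fits, for the most abundant species covering at least
    ``cumulative_share_pct`` of the family's abundance. A failing family is
    recorded and skipped, never fatal for the screen.
    """
    fam_map = traits.set_index("species")["family"]
    unknown = sorted(set(fish["species"]) - set(fam_map.index))
    if unknown:
        raise ValueError(f"species missing from traits checklist: {unknown}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    fish = fish.assign(family=fish["species"].map(fam_map))
    total_abund = fish["count"].sum()
    cells = benthic[CELL_COLUMNS + ["hard_coral"]]

    result = ScreeningResult(alpha=alpha,
                             contribution_threshold_pct=contribution_threshold_pct,
                             cumulative_share_pct=cumulative_share_pct)

    for family, block in fish.groupby("family"):
        contribution = 100.0 * block["count"].sum() / total_abund
        fam_counts = block.groupby(CELL_COLUMNS)["count"].sum().reset_index()
        data = cells.merge(fam_counts, on=CELL_COLUMNS, how="left")
        data["count"] = data["count"].fillna(0).astype(int)
        try:
            fit = aic_select(data["count"], data["hard_coral"], data["year"],
                             distributions=distributions, quad_nodes=quad_nodes,
                             n_restarts=n_restarts, seed=rng)
            significant = bool(np.isfinite(fit.wald_p) and fit.wald_p < alpha)
            selected = significant and contribution > contribution_threshold_pct
            result.families.append(FamilyScreen(family, contribution, fit,
                                                significant, selected))
        except (ValueError, RuntimeError) as exc:
            result.families.append(FamilyScreen(family, contribution, None,
                                                False, False, error=str(exc)))
            continue

        if not selected:
            continue
        fam_total = block["count"].sum()
        shares = (block.groupby("species")["count"].sum()
                  .sort_values(ascending=False) / fam_total * 100.0)
        cum = shares.cumsum()
        n_keep = int(np.searchsorted(cum.to_numpy(), cumulative_share_pct) + 1)
        for sp in shares.index[:n_keep]:
            sp_counts = block[block["species"] == sp].groupby(CELL_COLUMNS)["count"].sum().reset_index()
            sdata = cells.merge(sp_counts, on=CELL_COLUMNS, how="left")
            sdata["count"] = sdata["count"].fillna(0).astype(int)
            try:
                sfit = aic_select(sdata["count"], sdata["hard_coral"], sdata["year"],
                                  distributions=distributions, quad_nodes=quad_nodes,
                                  n_restarts=n_restarts, seed=rng)
                sig = bool(np.isfinite(sfit.wald_p) and sfit.wald_p < alpha)
                result.species.append(SpeciesScreen(sp, family, float(shares[sp]),
                                                    sfit, sig))
            except (ValueError, RuntimeError) as exc:
                result.species.append(SpeciesScreen(sp, family, float(shares[sp]),
                                                    None, False, error=str(exc)))
    return result
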