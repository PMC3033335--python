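"""Two-component Frechet mixture model of intron lengths.

Intron-length histograms typically show a sharp short-intron population and
a heavy long-intron tail; both are captured well by Frechet (inverse
Weibull) laws, so the species-level length distribution is modelled as a
two-component mixture, fit by maximum likelihood (EM with numerically
maximised component steps).  The per-intron length score is the log-odds of
the fitted discrete density against a uniform background
``c = 1 / (L_max - L_min)``, where ``L_min = 30`` and ``L_max`` is the 99%
quantile of the fitted longer component.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

L_MIN_DEFAULT = 30


@dataclass
class FrechetComponent:
    """Three-parameter Frechet law: shape alpha, scale sigma, location m."""

    shape: float
    scale: float
    location: float

    def dist(self) -> stats.rv_continuous:
        return stats.invweibull(c=self.shape, loc=self.location, scale=self.scale)

    def pdf(self, x: np.ndarray) -> np.ndarray:
        return self.dist().pdf(x)

    def cdf(self, x: np.ndarray) -> np.ndarray:
        return self.dist().cdf(x)

    def quantile(self, q: float) -> float:
        return float(self.dist().ppf(q))

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        u = rng.random(n)
        return self.location + self.scale * (-np.log(u)) ** (-1.0 / self.shape)


@dataclass
class LengthModel:
    """Two-component Frechet mixture with a uniform background density.

    ``weight`` is the mixing proportion of the *short* component (the one
    with the smaller median).  The discrete density assigns to integer
    length ``l`` the mixture CDF mass of ``[l, l+1)``, renormalised over
    ``[L_min, L_max)``.
    """

    short: FrechetComponent
    long: FrechetComponent
    weight: float  # P(short component)
    l_min: int = L_MIN_DEFAULT
    l_max: int | None = None
    _pmf_cache: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if not (0.0 <= self.weight <= 1.0):
            raise ValueError("mixture weight must lie in [0, 1]")
        if self.l_max is None:
            self.l_max = max(int(np.ceil(self.long.quantile(0.99))), self.l_min + 2)
        if self.l_max <= self.l_min:
            raise ValueError("l_max must exceed l_min")

    @property
    def background_density(self) -> float:
        """Uniform competitor density c = 1/(L_max - L_min)."""
        return 1.0 / (self.l_max - self.l_min)

    def mixture_pdf(self, x: np.ndarray) -> np.ndarray:
        return self.weight * self.short.pdf(x) + (1 - self.weight) * self.long.pdf(x)

    def mixture_cdf(self, x: np.ndarray) -> np.ndarray:
        return self.weight * self.short.cdf(x) + (1 - self.weight) * self.long.cdf(x)

    def discrete_density(self) -> np.ndarray:
        """Normalised pmf over integer lengths in [l_min, l_max)."""
        if self._pmf_cache is None:
            grid = np.arange(self.l_min, self.l_max + 1, dtype=float)
            cdf = self.mixture_cdf(grid)
            pmf = np.diff(cdf)
            total = pmf.sum()
            if total <= 0:
                raise ValueError("degenerate length model: no mass on [l_min, l_max)")
            self._pmf_cache = pmf / total
        return self._pmf_cache

    def density_at(self, l: int) -> float:
        if not (self.l_min <= l < self.l_max):
            raise ValueError(f"length {l} outside [{self.l_min}, {self.l_max})")
        return float(self.discrete_density()[l - self.l_min])

    def score(self, l: int) -> tuple[float, bool]:
        """Length log-odds log2(f(l)/c) in bits.

        Returns (score, in_range).  Out-of-range lengths receive the most
        penalised in-range score so that candidate comparison stays total.
        """
        pmf = self.discrete_density()
        c = self.background_density
        if self.l_min <= l < self.l_max:
            f = pmf[l - self.l_min]
            f = max(f, 1e-300)
            return float(np.log2(f / c)), True
        worst = float(np.log2(max(pmf.min(), 1e-300) / c))
        return worst, False

    def sample(self, n: int, rng: np.random.Generator,
               min_length: int = 31) -> np.ndarray:
        """Integer lengths >= min_length (draws below are resampled)."""
        out = np.empty(n, dtype=np.int64)
        filled = 0
        while filled < n:
            need = n - filled
            comp = rng.random(need) < self.weight
            draws = np.where(comp,
                             self.short.sample(need, rng),
                             self.long.sample(need, rng))
            draws = np.floor(draws).astype(np.int64)
            ok = draws >= min_length
            k = int(ok.sum())
            out[filled:filled + k] = draws[ok]
            filled += k
        return out


# ---------------------------------------------------------------------------
# maximum-likelihood fitting


def _neg_loglik_component(params: np.ndarray, x: np.ndarray, w: np.ndarray,
                          loc_cap: float) -> float:
    la, ls, m_raw = params
    alpha, sigma = np.exp(la), np.exp(ls)
    m = loc_cap / (1.0 + np.exp(-m_raw))  # location in (0, loc_cap)
    z = (x - m) / sigma
    if np.any(z <= 0):
        return 1e12
    logpdf = (np.log(alpha / sigma) - (1 + alpha) * np.log(z) - z ** (-alpha))
    val = -(w * logpdf).sum()
    return val if np.isfinite(val) else 1e12


def _fit_component(x: np.ndarray, w: np.ndarray,
                   init: FrechetComponent) -> FrechetComponent:
    loc_cap = float(x.min()) - 0.25
    if loc_cap <= 0:
        loc_cap = 1e-3
    m0 = min(max(init.location, 1e-3), loc_cap * 0.999)
    p0 = np.array([np.log(init.shape), np.log(init.scale),
                   np.log(m0 / (loc_cap - m0))])
    res = optimize.minimize(
        _neg_loglik_component, p0, args=(x, w, loc_cap),
        method="Nelder-Mead",
        options={"maxiter": 2000, "xatol": 1e-6, "fatol": 1e-8})
    la, ls, m_raw = res.x
    return FrechetComponent(shape=float(np.exp(la)), scale=float(np.exp(ls)),
                            location=float(loc_cap / (1.0 + np.exp(-m_raw))))


def _moment_init(x: np.ndarray) -> FrechetComponent:
    m = float(x.min()) - max(1.0, 0.02 * float(np.median(x) - x.min()))
    shifted = x - m
    # crude shape from the tail ratio of quantiles, clamped to a sane range
    q50, q90 = np.quantile(shifted, [0.5, 0.9])
    ratio = max(q90 / max(q50, 1e-9), 1.05)
    alpha = float(np.clip(np.log(np.log(1 / 0.9) / np.log(1 / 0.5)) /
                          -np.log(ratio), 0.3, 20.0))
    sigma = float(q50 * np.log(2.0) ** (1.0 / alpha))
    return FrechetComponent(shape=alpha, scale=max(sigma, 1e-3),
                            location=max(m, 0.0))


def mixture_log_likelihood(model: LengthModel, lengths: np.ndarray) -> float:
    x = np.asarray(lengths, dtype=float)
    pdf = model.mixture_pdf(x)
    return float(np.log(np.maximum(pdf, 1e-300)).sum())


def fit_length_model(lengths: np.ndarray, l_min: int = L_MIN_DEFAULT,
                     n_restarts: int = 3, max_em_iter: int = 60,
                     tol: float = 1e-7, seed: int = 0) -> LengthModel:
    """Fit the two-component Frechet mixture by EM.

    Initialisation splits the sample at several quantiles (each side fit as
    one Frechet) plus a log-scale 2-means split; the best converged
    log-likelihood wins.  Raises ``ValueError`` on degenerate input
    (fewer than 2 distinct lengths) and ``RuntimeError`` if no restart
    converges to a usable mixture.
    """
    x = np.asarray(lengths, dtype=float)
    if len(x) < 10:
        raise ValueError("need at least 10 lengths to fit a mixture")
    if np.unique(x).size < 2:
        raise ValueError("degenerate input: all lengths identical")

    rng = np.random.default_rng(seed)
    split_qs = [0.5, 0.7, 0.85][:max(1, n_restarts)]
    best: tuple[float, LengthModel] | None = None

    for q in split_qs:
        cut = np.quantile(x, q)
        lo, hi = x[x <= cut], x[x > cut]
        if len(lo) < 5 or len(hi) < 5:
            # fall back to a random split
            mask = rng.random(len(x)) < 0.5
            lo, hi = x[mask], x[~mask]
            if len(lo) < 5 or len(hi) < 5:
                continue
        try:
            comp_s = _fit_component(lo, np.ones(len(lo)), _moment_init(lo))
            comp_l = _fit_component(hi, np.ones(len(hi)), _moment_init(hi))
        except Exception:
            continue
        pi = len(lo) / len(x)

        # EM refinement
        prev_ll = -np.inf
        for _ in range(max_em_iter):
            p_s = pi * comp_s.pdf(x)
            p_l = (1 - pi) * comp_l.pdf(x)
            tot = p_s + p_l
            tot = np.maximum(tot, 1e-300)
            r = p_s / tot
            ll = float(np.log(tot).sum())
            if abs(ll - prev_ll) < tol * len(x):
                break
            prev_ll = ll
            pi = float(np.clip(r.mean(), 1e-6, 1 - 1e-6))
            comp_s = _fit_component(x, r, comp_s)
            comp_l = _fit_component(x, 1 - r, comp_l)

        # orient: 'short' is the component with the smaller median
        if comp_s.quantile(0.5) > comp_l.quantile(0.5):
            comp_s, comp_l = comp_l, comp_s
            pi = 1 - pi
        try:
            model = LengthModel(short=comp_s, long=comp_l, weight=pi, l_min=l_min)
        except ValueError:
            continue
        ll = mixture_log_likelihood(model, x)
        if best is None or ll > best[0]:
            best = (ll, model)

    if best is None:
        raise RuntimeError("Frechet mixture fit failed to converge from any start")
    return best[1]
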