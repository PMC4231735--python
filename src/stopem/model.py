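"""Two-channel Poisson mixture model for modification calling.

Each nucleotide x carries drop-off counts d_x and coverages n_x in a
chemically treated and a solvent control channel. Counts are modelled as
Poisson with coverage as exposure, d ~ Poisson(lambda * n), where lambda is
one of two RNA-wide drop-off rates: a background rate ``lambda_low`` and a
strong-stop rate ``lambda_high``, assumed approximately constant along the
RNA. Three latent classes tie the channels together:

==========  =============  =============  ==================================
class       treated rate   control rate   interpretation
==========  =============  =============  ==================================
U           lambda_low     lambda_low     unmodified background
H           lambda_high    lambda_high    natural strong stop / RT pause
M           lambda_high    lambda_low     chemically modified
==========  =============  =============  ==================================

The fourth combination (low treated / high control) is intentionally absent;
positions resembling it are absorbed by U/H. An EM algorithm estimates the
rates and the class weights and yields per-nucleotide class posteriors;
a nucleotide is called modified when its posterior probability of class M
strictly exceeds a threshold (default 0.90).

Everything is computed in log space (log-gamma Poisson terms), so large
counts cannot overflow.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import poisson

from .tracks import ChannelPair, ModificationCallSet, TranscriptRef

CLASS_NAMES = ("U", "H", "M")
_WEIGHT_FLOOR = 1e-12
_MONOTONE_SLACK = 1e-8


@dataclass(frozen=True)
class MixtureParams:
    """Parameters of the three-class two-channel Poisson mixture.

    The ordering constraint lambda_high >= lambda_low is enforced at
    construction by swapping the rates and relabelling the U/H weights if
    violated, so a label-swapped initialization converges to the same fit.
    """

    lambda_low: float
    lambda_high: float
    weights: np.ndarray = field(default_factory=lambda: np.array([0.90, 0.05, 0.05]))

    def __post_init__(self) -> None:
        if self.lambda_low <= 0 or self.lambda_high <= 0:
            raise ValueError("drop-off rates must be positive")
        w = np.asarray(self.weights, dtype=float)
        if w.shape != (3,) or (w < 0).any() or abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("weights must be a length-3 simplex vector")
        lo, hi = self.lambda_low, self.lambda_high
        if hi < lo:
            lo, hi = hi, lo
            w = w[[1, 0, 2]]
        object.__setattr__(self, "lambda_low", float(lo))
        object.__setattr__(self, "lambda_high", float(hi))
        object.__setattr__(self, "weights", w)

    @property
    def rate_table(self) -> np.ndarray:
        """(3, 2) array of (treated, control) rates per class U, H, M."""
        lo, hi = self.lambda_low, self.lambda_high
        return np.array([[lo, lo], [hi, hi], [hi, lo]])


class TwoChannelPoissonEM:
    """EM model for paired treated/control RT drop-off counts.

    Parameters
    ----------
    d_t, n_t : per-position stop counts and coverage, treated channel
    d_c, n_c : same for the control channel
    transcript : optional TranscriptRef for base annotation in outputs
    sample_name : label carried into results and call sets

    Positions with zero coverage in either channel are excluded from the
    likelihood and carry no posterior.
    """

    def __init__(
        self,
        d_t,
        n_t,
        d_c,
        n_c,
        transcript: TranscriptRef | None = None,
        sample_name: str = "sample",
    ) -> None:
        self.d_t = np.asarray(d_t, dtype=np.int64)
        self.n_t = np.asarray(n_t, dtype=np.int64)
        self.d_c = np.asarray(d_c, dtype=np.int64)
        self.n_c = np.asarray(n_c, dtype=np.int64)
        if not (self.d_t.shape == self.n_t.shape == self.d_c.shape == self.n_c.shape):
            raise ValueError("all four count vectors must have the same length")
        self.nobs = self.d_t.size
        self.usable = (self.n_t > 0) & (self.n_c > 0)
        self.transcript = transcript
        self.sample_name = sample_name

    @classmethod
    def from_pair(cls, pair: ChannelPair) -> "TwoChannelPoissonEM":
        return cls(
            pair.treated.stops,
            pair.treated.coverage,
            pair.control.stops,
            pair.control.coverage,
            transcript=pair.transcript,
            sample_name=pair.sample_name,
        )

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        treated=("stops_T", "cov_T"),
        control=("stops_C", "cov_C"),
        **kwargs,
    ) -> "TwoChannelPoissonEM":
        return cls(df[treated[0]], df[treated[1]], df[control[0]], df[control[1]], **kwargs)

    # ---- likelihood machinery -------------------------------------------

    def _class_loglik(self, params: MixtureParams) -> np.ndarray:
        """(n_usable, 3) per-class joint log-likelihood including log-weight."""
        u = self.usable
        table = params.rate_table
        out = np.empty((int(u.sum()), 3))
        with np.errstate(divide="ignore"):
            logw = np.log(np.maximum(params.weights, _WEIGHT_FLOOR))
        for k in range(3):
            lam_t, lam_c = table[k]
            out[:, k] = (
                logw[k]
                + poisson.logpmf(self.d_t[u], lam_t * self.n_t[u])
                + poisson.logpmf(self.d_c[u], lam_c * self.n_c[u])
            )
        return out

    def loglik(self, params: MixtureParams) -> float:
        """Total mixture log-likelihood over usable positions."""
        ll = float(logsumexp(self._class_loglik(params), axis=1).sum())
        if not np.isfinite(ll):
            raise FloatingPointError("non-finite log-likelihood")
        return ll

    def e_step(self, params: MixtureParams) -> np.ndarray:
        """Per-position class posteriors, shape (nobs, 3); NaN where unusable."""
        cl = self._class_loglik(params)
        log_post = cl - logsumexp(cl, axis=1, keepdims=True)
        gamma = np.full((self.nobs, 3), np.nan)
        gamma[self.usable] = np.exp(log_post)
        return gamma

    def m_step(
        self,
        posterior: np.ndarray,
        prev: MixtureParams | None = None,
        fix_weights: bool = False,
    ) -> MixtureParams:
        """Closed-form weighted-ratio parameter updates.

        lambda_low pools the U class (both channels) with the M class
        control channel; lambda_high pools the H class (both channels) with
        the M class treated channel. A vanished class keeps its previous
        rate and gets a floored weight.
        """
        u = self.usable
        g = posterior[u]
        d_t, n_t, d_c, n_c = self.d_t[u], self.n_t[u], self.d_c[u], self.n_c[u]

        num_low = (g[:, 0] * (d_t + d_c)).sum() + (g[:, 2] * d_c).sum()
        den_low = (g[:, 0] * (n_t + n_c)).sum() + (g[:, 2] * n_c).sum()
        num_high = (g[:, 1] * (d_t + d_c)).sum() + (g[:, 2] * d_t).sum()
        den_high = (g[:, 1] * (n_t + n_c)).sum() + (g[:, 2] * n_t).sum()

        if den_low > 0:
            lam_low = max(num_low / den_low, 1e-12)
        else:
            lam_low = prev.lambda_low if prev is not None else 1e-6
        if den_high > 0:
            lam_high = max(num_high / den_high, 1e-12)
        else:
            lam_high = prev.lambda_high if prev is not None else 1e-3

        if fix_weights and prev is not None:
            w = prev.weights
        else:
            w = g.mean(axis=0)
            w = np.maximum(w, _WEIGHT_FLOOR)
            w = w / w.sum()
        return MixtureParams(lambda_low=lam_low, lambda_high=lam_high, weights=w)

    def auto_init(self) -> MixtureParams:
        """Deterministic initialization from pooled per-position rates.

        lambda_low = 25th percentile and lambda_high = 99th percentile of
        the pooled (both-channel) drop-off rates, floored at 1e-6 and kept
        apart; weights (0.90, 0.05, 0.05).
        """
        u = self.usable
        pooled = (self.d_t[u] + self.d_c[u]) / (self.n_t[u] + self.n_c[u])
        lam_low = max(float(np.percentile(pooled, 25)), 1e-6)
        lam_high = max(float(np.percentile(pooled, 99)), 2 * lam_low)
        return MixtureParams(lambda_low=lam_low, lambda_high=lam_high)

    # ---- fitting ---------------------------------------------------------

    def fit(
        self,
        init: MixtureParams | None = None,
        tol: float = 1e-8,
        max_iter: int = 1000,
        fix_weights: bool = False,
        restarts: int = 0,
        seed: int | None = None,
    ) -> "TwoChannelPoissonEMResults":
        """Run EM to convergence (relative log-likelihood change < tol).

        ``restarts`` adds that many randomly perturbed initializations
        (seeded) on top of the deterministic one; the best-likelihood fit
        is returned. The default is fully deterministic.
        """
        if tol <= 0:
            raise ValueError("tol must be positive")
        if int(self.usable.sum()) < 10:
            raise ValueError(
                f"only {int(self.usable.sum())} positions with coverage in both "
                "channels; need >= 10"
            )
        inits = [init if init is not None else self.auto_init()]
        if restarts > 0:
            rng = np.random.default_rng(seed)
            base = inits[0]
            for _ in range(restarts):
                f_low, f_high = rng.lognormal(0.0, 0.5, size=2)
                w = rng.dirichlet([9.0, 0.5, 0.5])
                inits.append(
                    MixtureParams(base.lambda_low * f_low, base.lambda_high * f_high, w)
                )
        best = None
        for start in inits:
            res = self._fit_single(start, tol, max_iter, fix_weights)
            if best is None or res.llf > best.llf:
                best = res
        return best

    def _fit_single(self, params, tol, max_iter, fix_weights):
        trace: list[float] = []
        posterior = None
        converged = False
        prev_ll = None
        for _ in range(max_iter):
            posterior = self.e_step(params)
            ll = self.loglik(params)
            if prev_ll is not None and ll < prev_ll - _MONOTONE_SLACK * abs(prev_ll):
                raise AssertionError(
                    f"EM log-likelihood decreased: {prev_ll} -> {ll}"
                )
            trace.append(ll)
            if prev_ll is not None and abs(ll - prev_ll) < tol * abs(prev_ll):
                converged = True
                break
            params = self.m_step(posterior, prev=params, fix_weights=fix_weights)
            prev_ll = ll
        return TwoChannelPoissonEMResults(
            model=self,
            params=params,
            posteriors=posterior,
            llf=trace[-1],
            log_likelihood_trace=np.array(trace),
            converged=converged,
            n_iterations=len(trace),
        )


@dataclass
class TwoChannelPoissonEMResults:
    """Fitted mixture: parameters, per-nucleotide posteriors, diagnostics."""

    model: TwoChannelPoissonEM
    params: MixtureParams
    posteriors: np.ndarray  # (nobs, 3), NaN rows where unusable
    llf: float
    log_likelihood_trace: np.ndarray
    converged: bool
    n_iterations: int

    @property
    def defined_mask(self) -> np.ndarray:
        return self.model.usable

    @property
    def p_modified(self) -> np.ndarray:
        return self.posteriors[:, 2]

    def call_modified(
        self, threshold: float = 0.90, on: str = "p_modified"
    ) -> ModificationCallSet:
        """Threshold the modification posterior into binary calls.

        ``on="p_modified"`` (default) thresholds the M-class posterior;
        ``on="one_minus_p_unmodified"`` thresholds 1 - P(U) instead. A call
        requires the statistic to be STRICTLY greater than the threshold.
        """
        if not (0.0 < threshold < 1.0):
            raise ValueError("threshold must lie strictly inside (0, 1)")
        if on == "p_modified":
            stat = self.posteriors[:, 2]
        elif on == "one_minus_p_unmodified":
            stat = 1.0 - self.posteriors[:, 0]
        else:
            raise ValueError(f"unknown calling statistic {on!r}")
        called = np.zeros(self.model.nobs, dtype=bool)
        d = self.defined_mask
        called[d] = stat[d] > threshold
        transcript = self.model.transcript
        if transcript is None:
            transcript = TranscriptRef("unnamed", "N" * self.model.nobs)
        return ModificationCallSet(
            transcript=transcript,
            p_modified=self.posteriors[:, 2],
            called=called,
            threshold=threshold,
            sample_name=self.model.sample_name,
        )

    def to_frame(self) -> pd.DataFrame:
        """Per-position table: counts, coverages and class posteriors."""
        m = self.model
        df = pd.DataFrame(
            {
                "position": np.arange(1, m.nobs + 1),
                "d_T": m.d_t,
                "n_T": m.n_t,
                "d_C": m.d_c,
                "n_C": m.n_c,
                "p_U": self.posteriors[:, 0],
                "p_H": self.posteriors[:, 1],
                "p_M": self.posteriors[:, 2],
            }
        )
        if m.transcript is not None:
            df.insert(1, "base", [m.transcript.base(p) for p in df["position"]])
        return df

    def summary(self) -> str:
        p = self.params
        w = p.weights
        lines = [
            "Two-channel Poisson mixture (EM)",
            "=" * 40,
            f"sample:            {self.model.sample_name}",
            f"positions used:    {int(self.model.usable.sum())} / {self.model.nobs}",
            f"lambda_low:        {p.lambda_low:.6g}",
            f"lambda_high:       {p.lambda_high:.6g}",
            f"pi_U / pi_H / pi_M: {w[0]:.4f} / {w[1]:.4f} / {w[2]:.4f}",
            f"log-likelihood:    {self.llf:.4f}",
            f"iterations:        {self.n_iterations} (converged: {self.converged})",
        ]
        return "\n".join(lines)
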