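"""Type-1 quantitative BRET: correction, normalization, and stoichiometry fitting.

In a type-1 qBRET titration, donor (NanoLuc-tagged) and acceptor
(HaloTag-618-labelled) fusion constructs are co-expressed at varying plasmid
ratios while total expression is held constant. After subtracting the
dye-free background BRET and putting luminescence and fluorescence on a
common expression scale, the corrected BRET signal is analyzed as a function
of the acceptor fraction

    f = acceptor_norm / (donor_norm + acceptor_norm).

Ideal curves under random assembly of an n-mer: a donor in an n-mer has
n - 1 partner slots, each acceptor-occupied with probability f, so

    BRET(f) = bmax * [1 - (1 - f)^(n-1)]        (n >= 2)

— the probability that at least one partner is an acceptor, scaled by the
saturating amplitude bmax. A dimer (n = 2) therefore saturates
hyperbolically against the acceptor:donor ratio rho = f/(1-f):
bmax * rho/(1+rho). A monomer produces only non-specific bystander BRET,
linear in the acceptor level and hence in rho:

    BRET(rho) = bystander_slope * rho           (n = 1).

Model selection is least squares per candidate n with AICc comparison.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

logger = logging.getLogger(__name__)

TITRATION_COLUMNS = (
    "donor_lum",
    "acceptor_fluor",
    "bret_raw",
    "bret_background",
    "bret_corr",
    "donor_norm",
    "acceptor_norm",
    "total_expr",
    "acceptor_fraction",
    "ratio",
)


class InsufficientDataError(ValueError):
    """Too few titration points for the requested analysis."""


def ideal_curve(
    model_n: int,
    bmax: float = 1.0,
    bystander_slope: float = 0.0,
    f: float | np.ndarray = 0.0,
) -> np.ndarray:
    """Noise-free BRET at acceptor fraction ``f`` under the ``model_n``-mer.

    ``f`` must lie in [0, 1]; for the monomer model f = 1 (infinite
    acceptor:donor ratio) is a pole and raises a domain error.
    """
    f = np.asarray(f, dtype=float)
    if np.any((f < 0) | (f > 1)):
        raise ValueError("acceptor fraction f must lie in [0, 1]")
    if model_n < 1:
        raise ValueError("model_n must be >= 1")
    if model_n == 1:
        if np.any(f >= 1.0):
            raise ValueError("monomer model diverges at f = 1")
        return bystander_slope * f / (1.0 - f)
    return bmax * (1.0 - (1.0 - f) ** (model_n - 1))


@dataclass
class StoichFit:
    """Result of comparing ideal stoichiometry curves to one titration."""

    model_n: int
    bmax: float
    bystander_slope: float
    rss: float
    aicc: float
    classification: int | None
    n_points: int
    f_span: float
    per_model: pd.DataFrame
    rapid_saturation_flag: bool = False


class StoichiometryModel(BaseEstimator, RegressorMixin):
    """Scikit-learn style estimator for BRET stoichiometry classification.

    Fits each candidate n-mer curve (and the monomer bystander line) to
    corrected BRET vs acceptor fraction by least squares and classifies the
    complex order by lowest AICc.

    Parameters
    ----------
    candidate_ns : tuple of int
        Complex orders to fit; 1 denotes the monomer/bystander model.
    min_points : int
        Minimum titration points required to classify.
    min_f_span : float
        Minimum range of acceptor fractions required to classify; below it
        fits are still reported but ``best_n_`` is None.

    Attributes
    ----------
    fits_ : pandas.DataFrame
        One row per candidate model: parameters, rss, aicc.
    best_n_ : int or None
        AICc-minimal model order (None when the span is insufficient).
    bmax_, bystander_slope_ : float
        Parameters of the winning model.
    rapid_saturation_ : bool
        True when the winning order is >= 3 but the acceptor-fraction
        coverage is too sparse near saturation to trust the exact order.
    """

    def __init__(
        self,
        candidate_ns: tuple[int, ...] = (1, 2, 3, 4),
        min_points: int = 5,
        min_f_span: float = 0.4,
    ) -> None:
        self.candidate_ns = candidate_ns
        self.min_points = min_points
        self.min_f_span = min_f_span

    def fit(self, X, y):
        """Fit all candidate curves.

        ``X`` is the acceptor fraction (1 column or 1-D), ``y`` the
        corrected BRET signal.
        """
        f = np.asarray(X, dtype=float).reshape(-1)
        y = np.asarray(y, dtype=float).reshape(-1)
        if f.shape != y.shape:
            raise ValueError("X and y must have the same length")
        if len(f) < self.min_points:
            raise InsufficientDataError(
                f"need >= {self.min_points} points, got {len(f)}"
            )
        if np.any((f < 0) | (f > 1)):
            raise ValueError("acceptor fractions must lie in [0, 1]")

        n_pts = len(f)
        rows = []
        for n in self.candidate_ns:
            if n == 1:
                usable = f < 1.0
                rho = f[usable] / (1.0 - f[usable])
                denom = float(rho @ rho)
                slope = float(rho @ y[usable]) / denom if denom > 0 else 0.0
                resid = y[usable] - slope * rho
                rss = float(resid @ resid) + float(y[~usable] @ y[~usable])
                rows.append({"model_n": 1, "bmax": np.nan, "bystander_slope": slope, "rss": rss})
            else:
                g = 1.0 - (1.0 - f) ** (n - 1)
                denom = float(g @ g)
                bmax = float(g @ y) / denom if denom > 0 else 0.0
                resid = y - bmax * g
                rss = float(resid @ resid)
                rows.append(
                    {"model_n": n, "bmax": bmax, "bystander_slope": np.nan, "rss": rss}
                )
        fits = pd.DataFrame(rows)
        # one fitted curve parameter + residual variance
        k = 2.0
        with np.errstate(divide="ignore"):
            loglik_term = n_pts * np.log(np.maximum(fits["rss"], 1e-300) / n_pts)
        correction = (
            2 * k * (k + 1) / (n_pts - k - 1) if n_pts - k - 1 > 0 else np.inf
        )
        fits["aicc"] = loglik_term + 2 * k + correction
        self.fits_ = fits
        self.f_span_ = float(f.max() - f.min())
        self.n_points_ = n_pts

        best = fits.loc[fits["aicc"].idxmin()]
        if self.f_span_ < self.min_f_span:
            logger.warning(
                "acceptor-fraction span %.2f < %.2f: classification refused",
                self.f_span_,
                self.min_f_span,
            )
            self.best_n_ = None
        else:
            self.best_n_ = int(best["model_n"])
        self.bmax_ = float(best["bmax"])
        self.bystander_slope_ = float(best["bystander_slope"])
        self.rss_ = float(best["rss"])
        self.aicc_ = float(best["aicc"])
        # sparse coverage of the saturating limb makes high orders unreliable
        self.rapid_saturation_ = bool(
            self.best_n_ is not None
            and self.best_n_ >= 3
            and (self.f_span_ < 0.6 or float(f.max()) < 0.7)
        )
        return self

    def predict(self, X):
        """Predicted BRET of the winning (AICc-minimal) model."""
        check_is_fitted(self, "fits_")
        best = self.fits_.loc[self.fits_["aicc"].idxmin()]
        n = int(best["model_n"])
        f = np.asarray(X, dtype=float).reshape(-1)
        return ideal_curve(
            n,
            bmax=0.0 if np.isnan(best["bmax"]) else float(best["bmax"]),
            bystander_slope=0.0
            if np.isnan(best["bystander_slope"])
            else float(best["bystander_slope"]),
            f=f,
        )

    def to_result(self) -> StoichFit:
        check_is_fitted(self, "fits_")
        return StoichFit(
            model_n=int(self.fits_.loc[self.fits_["aicc"].idxmin(), "model_n"]),
            bmax=self.bmax_,
            bystander_slope=self.bystander_slope_,
            rss=self.rss_,
            aicc=self.aicc_,
            classification=self.best_n_,
            n_points=self.n_points_,
            f_span=self.f_span_,
            per_model=self.fits_.copy(),
            rapid_saturation_flag=self.rapid_saturation_,
        )


def correct_and_normalize(
    plate: pd.DataFrame,
    donor_calibration: float = 1.0,
    acceptor_calibration: float = 1.0,
) -> pd.DataFrame:
    """Turn a raw plate table into a corrected, normalized titration.

    ``plate`` holds one dye well and one matched dye-free (DMSO) background
    well per condition, with columns ``condition``, ``donor_lum``,
    ``acceptor_fluor``, ``bret`` and boolean ``is_background``. The
    background BRET of each condition is subtracted from its dye well;
    conditions without a background pair are dropped with a log entry.
    Calibration factors place luminescence and fluorescence on a common
    expression scale (the study normalizes but reports no factors; defaults
    are 1.0).
    """
    required = {"condition", "donor_lum", "acceptor_fluor", "bret", "is_background"}
    missing = required - set(plate.columns)
    if missing:
        raise ValueError(f"plate table missing columns: {sorted(missing)}")
    rows = []
    for cond, grp in plate.groupby("condition", sort=True):
        sig = grp[~grp["is_background"]]
        bg = grp[grp["is_background"]]
        if len(sig) == 0 or len(bg) == 0:
            logger.warning("condition %s lacks a signal/background pair; dropped", cond)
            continue
        bret_raw = float(sig["bret"].mean())
        bret_background = float(bg["bret"].mean())
        donor_norm = float(sig["donor_lum"].mean()) * donor_calibration
        acceptor_norm = float(sig["acceptor_fluor"].mean()) * acceptor_calibration
        total = donor_norm + acceptor_norm
        rows.append(
            {
                "condition": cond,
                "donor_lum": float(sig["donor_lum"].mean()),
                "acceptor_fluor": float(sig["acceptor_fluor"].mean()),
                "bret_raw": bret_raw,
                "bret_background": bret_background,
                "bret_corr": bret_raw - bret_background,
                "donor_norm": donor_norm,
                "acceptor_norm": acceptor_norm,
                "total_expr": total,
                "acceptor_fraction": acceptor_norm / total if total > 0 else np.nan,
                "ratio": acceptor_norm / donor_norm if donor_norm > 0 else np.inf,
            }
        )
    out = pd.DataFrame(rows)
    if len(out) == 0:
        raise ValueError("no usable conditions in plate table")
    return out.sort_values("acceptor_fraction", ignore_index=True)


def filter_by_ratio(titration: pd.DataFrame, min_ratio: float = 2.0) -> pd.DataFrame:
    """Points with acceptor:donor expression ratio strictly above ``min_ratio``.

    Used for the constant-total-expression check (acceptor fluorescence is
    the less sensitive readout, so low-ratio points are unreliable there);
    curve fitting keeps the full set. Returns an empty frame with a warning
    when nothing survives.
    """
    if "ratio" not in titration.columns:
        raise ValueError("titration has no 'ratio' column; run correct_and_normalize")
    kept = titration[titration["ratio"] > min_ratio].reset_index(drop=True)
    if len(kept) == 0:
        logger.warning("ratio filter > %.3g removed every point", min_ratio)
    return kept


def constant_expression_ftest(titration: pd.DataFrame) -> tuple[float, float]:
    """Nested-model F-test of total expression vs acceptor:donor ratio.

    Compares a horizontal (mean-only) fit of ``total_expr`` against a
    straight-line fit in ``ratio``; a large p-value is consistent with the
    constant-total design. Requires >= 3 points.
    """
    if len(titration) < 3:
        raise InsufficientDataError("constant-expression F-test needs >= 3 points")
    y = titration["total_expr"].to_numpy(dtype=float)
    x = titration["ratio"].to_numpy(dtype=float)
    n = len(y)
    rss0 = float(np.sum((y - y.mean()) ** 2))
    X = np.column_stack([np.ones(n), x])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    rss1 = float(np.sum((y - X @ beta) ** 2))
    if rss1 <= 0:
        if rss0 <= 0:
            return 0.0, 1.0
        return np.inf, 0.0
    F = (rss0 - rss1) / (rss1 / (n - 2))
    F = max(F, 0.0)
    p = float(stats.f.sf(F, 1, n - 2))
    return float(F), p


def fit_stoichiometry(
    titration: pd.DataFrame,
    candidate_ns: tuple[int, ...] = (1, 2, 3, 4),
    min_f_span: float = 0.4,
) -> StoichFit:
    """Fit ideal curves to a corrected titration and classify complex order.

    Thin wrapper over :class:`StoichiometryModel` operating on the
    ``acceptor_fraction`` / ``bret_corr`` columns.
    """
    if not {"acceptor_fraction", "bret_corr"} <= set(titration.columns):
        raise ValueError("titration needs 'acceptor_fraction' and 'bret_corr' columns")
    est = StoichiometryModel(candidate_ns=candidate_ns, min_f_span=min_f_span)
    est.fit(titration["acceptor_fraction"].to_numpy(), titration["bret_corr"].to_numpy())
    return est.to_result()
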