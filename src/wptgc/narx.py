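"""Polynomial NAR/NARX models with FROLS structure detection.

Models are linear-in-parameters expansions over lagged outputs, lagged
inputs and their pairwise (degree-2) products.  Structure detection uses
forward-regression orthogonal least squares: at each step every remaining
candidate regressor is Gram-Schmidt-orthogonalized against the selected
set and scored by its error-reduction ratio (ERR); the best candidate is
appended until the unexplained-energy ratio drops below ``rho`` or
``n_max`` terms are reached.  Parameters come from back-substitution of
the unit upper-triangular system, or (default) a final least-squares
refit on the selected columns.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations_with_replacement, product

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "ModelTerm",
    "CandidateSet",
    "StopRule",
    "FROLSResult",
    "NARXModel",
    "build_candidates",
    "build_design",
    "err_score",
    "frols",
    "solve_parameters",
    "fit_nar",
    "fit_narx",
    "predict",
]


@dataclass(frozen=True)
class ModelTerm:
    """One polynomial regressor: a product of lagged samples.

    ``y_lags`` index the modelled (output) series, ``x_lags`` the
    exogenous series.  Lags are stored sorted so that algebraically equal
    products compare equal, e.g. y(t-1)y(t-2) == y(t-2)y(t-1).
    """

    y_lags: tuple[int, ...] = ()
    x_lags: tuple[int, ...] = ()

    def __post_init__(self):
        object.__setattr__(self, "y_lags", tuple(sorted(self.y_lags)))
        object.__setattr__(self, "x_lags", tuple(sorted(self.x_lags)))
        if self.degree not in (1, 2):
            raise ValueError(f"term degree must be 1 or 2, got {self.degree}")
        if any(l < 1 for l in self.y_lags + self.x_lags):
            raise ValueError("lags must be positive")

    @property
    def degree(self) -> int:
        return len(self.y_lags) + len(self.x_lags)

    @property
    def uses_input(self) -> bool:
        return len(self.x_lags) > 0

    def label(self) -> str:
        parts = [f"y(t-{l})" for l in self.y_lags]
        parts += [f"x(t-{l})" for l in self.x_lags]
        return "*".join(parts)

    def __repr__(self) -> str:  # compact in logs / reports
        return f"ModelTerm<{self.label()}>"


@dataclass
class CandidateSet:
    """Ordered dictionary of candidate model terms."""

    terms: list[ModelTerm]
    p: int
    q: int
    degree: int

    @property
    def M(self) -> int:
        return len(self.terms)

    @property
    def max_lag(self) -> int:
        return max(
            max((max(t.y_lags, default=0) for t in self.terms), default=0),
            max((max(t.x_lags, default=0) for t in self.terms), default=0),
        )

    def index_of(self, term: ModelTerm) -> int:
        return self.terms.index(term)


def build_candidates(p: int, q: int = 0, degree: int = 2,
                     include_input: bool | None = None) -> CandidateSet:
    """Build the polynomial term dictionary.

    NAR (q=0): {y(t-k)} plus all y*y pairs -> M = p + p(p+1)/2.
    NARX: adds {x(t-k)}, x*x pairs and y*x cross pairs
    -> M = p + q + p(p+1)/2 + q(q+1)/2 + p*q.
    """
    if p < 1:
        raise ValueError("p must be >= 1")
    if q < 0:
        raise ValueError("q must be >= 0")
    if degree not in (1, 2):
        raise ValueError(f"unsupported degree {degree}: the model is at most quadratic")
    if include_input is None:
        include_input = q > 0
    if include_input and q < 1:
        raise ValueError("include_input requires q >= 1")
    terms: list[ModelTerm] = [ModelTerm(y_lags=(k,)) for k in range(1, p + 1)]
    if include_input:
        terms += [ModelTerm(x_lags=(k,)) for k in range(1, q + 1)]
    if degree == 2:
        terms += [
            ModelTerm(y_lags=pair)
            for pair in combinations_with_replacement(range(1, p + 1), 2)
        ]
        if include_input:
            terms += [
                ModelTerm(x_lags=pair)
                for pair in combinations_with_replacement(range(1, q + 1), 2)
            ]
            terms += [
                ModelTerm(y_lags=(k,), x_lags=(j,))
                for k, j in product(range(1, p + 1), range(1, q + 1))
            ]
    return CandidateSet(terms=terms, p=p, q=q if include_input else 0,
                        degree=degree)


def _term_column(term: ModelTerm, y: np.ndarray, x: np.ndarray | None,
                 offset: int, n: int) -> np.ndarray:
    col = np.ones(n - offset)
    for l in term.y_lags:
        col = col * y[offset - l: n - l]
    for l in term.x_lags:
        if x is None:
            raise ValueError(f"term {term.label()} needs an input series")
        col = col * x[offset - l: n - l]
    return col


def build_design(y, x, cs: CandidateSet, offset: int | None = None):
    """Evaluate the candidate dictionary into a regressor matrix.

    Row t runs from ``offset`` (default: the dictionary's maximum lag) to
    the end of the series; the target is y(t).  Returns (Phi, target).
    """
    y = np.asarray(y, dtype=float).ravel()
    x = None if x is None else np.asarray(x, dtype=float).ravel()
    if x is not None and x.size != y.size:
        raise ValueError(f"length mismatch: y has {y.size}, x has {x.size}")
    if offset is None:
        offset = cs.max_lag
    if offset < cs.max_lag:
        raise ValueError(f"offset {offset} smaller than max lag {cs.max_lag}")
    n = y.size
    if n < offset + 2:
        raise ValueError(
            f"series of length {n} too short: need at least {offset + 2} "
            f"samples for max lag {offset}"
        )
    Phi = np.column_stack(
        [_term_column(t, y, x, offset, n) for t in cs.terms]
    )
    return Phi, y[offset:]


def err_score(y, phi) -> float:
    """Error-reduction ratio of one regressor against the target.

    (y.phi)^2 / ((y.y)(phi.phi)) — the squared normalized inner product,
    i.e. the fraction of target energy the regressor alone explains.
    """
    y = np.asarray(y, dtype=float).ravel()
    phi = np.asarray(phi, dtype=float).ravel()
    ny = float(np.linalg.norm(y))
    np_ = float(np.linalg.norm(phi))
    if ny == 0.0 or np_ == 0.0:
        raise ValueError("err_score undefined for zero-norm vector")
    # normalize first: (y.phi)^2 / ((y.y)(phi.phi)) without under/overflow
    c = float((y / ny) @ (phi / np_))
    return c * c


@dataclass
class StopRule:
    """Halt selection when 1 - sum(ERR) < rho, or at n_max terms.

    The default rho is tiny, so n_max is usually the binding cap: on
    band-limited (heavily oversampled) signals the output is often
    > 99 % predictable from its own lags alone and any energy-fraction
    threshold large enough to matter would stop selection before a
    genuinely informative input term could enter.
    """

    rho: float = 1e-6
    n_max: int = 10

    def __post_init__(self):
        if not 0 <= self.rho < 1:
            raise ValueError("rho must lie in [0, 1)")
        if self.n_max < 1:
            raise ValueError("n_max must be >= 1")


@dataclass
class FROLSResult:
    selected: list[int]
    err: np.ndarray
    q_vectors: np.ndarray          # columns q_1..q_n
    A: np.ndarray                  # unit upper-triangular
    g: np.ndarray
    theta: np.ndarray              # back-substitution estimates
    n: int
    skipped: list[int] = field(default_factory=list)

    @property
    def esr(self) -> float:
        """Unexplained-energy ratio 1 - sum(ERR)."""
        return float(1.0 - np.sum(self.err))


_DEGENERATE_NORM_RATIO = 1e-12


def frols(y, Phi, stop: StopRule | None = None) -> FROLSResult:
    """Forward-regression orthogonal least squares selection.

    Greedy: step 1 picks the raw-ERR maximizer; step s >= 2 scores every
    remaining candidate on its version orthogonalized against the
    selected q vectors.  Candidates whose orthogonalized norm collapses
    below 1e-12 of their original norm are skipped (near-collinear).
    """
    if stop is None:
        stop = StopRule()
    y = np.asarray(y, dtype=float).ravel()
    Phi = np.asarray(Phi, dtype=float)
    if Phi.ndim != 2 or Phi.shape[1] < 1:
        raise ValueError("Phi must be a 2-D matrix with at least one column")
    if Phi.shape[0] != y.size:
        raise ValueError("row count of Phi must match target length")
    yty = float(y @ y)
    if yty == 0.0:
        raise ValueError("target has zero energy; nothing to select")

    M = Phi.shape[1]
    Qc = Phi.copy()                        # running orthogonalized candidates
    orig_norm2 = np.sum(Phi ** 2, axis=0)
    alive = orig_norm2 > 0.0
    skipped = [int(i) for i in np.flatnonzero(~alive)]

    selected: list[int] = []
    errs: list[float] = []
    q_cols: list[np.ndarray] = []
    q_norm2: list[float] = []
    A_cols: list[np.ndarray] = []
    g_vals: list[float] = []

    while alive.any() and len(selected) < stop.n_max:
        norm2 = np.sum(Qc ** 2, axis=0)
        dead = alive & (norm2 < _DEGENERATE_NORM_RATIO ** 2 * orig_norm2)
        for i in np.flatnonzero(dead):
            logger.debug("FROLS: candidate %d degenerate after "
                         "orthogonalization, skipped", i)
            skipped.append(int(i))
        alive &= ~dead
        if not alive.any():
            break
        scores = np.full(M, -np.inf)
        idx = np.flatnonzero(alive)
        scores[idx] = (y @ Qc[:, idx]) ** 2 / (yty * norm2[idx])
        l = int(np.argmax(scores))
        q = Qc[:, l].copy()
        # classical GS; re-orthogonalize if accumulated loss is visible
        if q_cols:
            overlaps = np.array([abs(q @ qr) / np.sqrt((q @ q) * n2)
                                 for qr, n2 in zip(q_cols, q_norm2)])
            if overlaps.max() > 1e-8:
                for qr, n2 in zip(q_cols, q_norm2):
                    q = q - (q @ qr) / n2 * qr
        qq = float(q @ q)
        a_col = np.array([(Phi[:, l] @ qr) / n2
                          for qr, n2 in zip(q_cols, q_norm2)])
        g = float(y @ q) / qq
        selected.append(l)
        errs.append(g * g * qq / yty)
        A_cols.append(a_col)
        q_cols.append(q)
        q_norm2.append(qq)
        g_vals.append(g)
        alive[l] = False
        # deflate the surviving candidates against the new direction
        if alive.any():
            idx = np.flatnonzero(alive)
            coeffs = (q @ Qc[:, idx]) / qq
            Qc[:, idx] -= np.outer(q, coeffs)
        if 1.0 - sum(errs) < stop.rho:
            break

    if not selected:
        raise ValueError("FROLS selected no terms: all candidates degenerate")

    n = len(selected)
    A = np.eye(n)
    for s, col in enumerate(A_cols):
        A[: s, s] = col
    g_vec = np.asarray(g_vals)
    result = FROLSResult(
        selected=selected, err=np.asarray(errs),
        q_vectors=np.column_stack(q_cols), A=A, g=g_vec,
        theta=np.empty(0), n=n, skipped=skipped,
    )
    result.theta = solve_parameters(result)
    return result


def solve_parameters(fr: FROLSResult) -> np.ndarray:
    """Back-substitute the unit upper-triangular system A theta = g."""
    A, g = fr.A, fr.g
    n = g.size
    if A.shape != (n, n):
        raise ValueError("triangular system dimensions inconsistent")
    if np.any(np.abs(np.diag(A)) < 1e-300):
        raise np.linalg.LinAlgError("singular triangular system")
    theta = np.zeros(n)
    for s in range(n - 1, -1, -1):
        theta[s] = g[s] - A[s, s + 1:] @ theta[s + 1:]
    return theta


@dataclass
class NARXModel:
    """A fitted (selected-term) polynomial model of one series."""

    candidate_set: CandidateSet
    frols: FROLSResult
    terms: list[ModelTerm]
    theta: np.ndarray
    residuals: np.ndarray
    residual_variance: float
    offset: int
    refit: bool

    @property
    def valid_range(self) -> tuple[int, int]:
        return self.offset, self.offset + self.residuals.size

    def report(self) -> dict:
        """Human-readable summary (JSON-serializable)."""
        fr = self.frols
        err_map = {self.candidate_set.terms[l].label(): float(e)
                   for l, e in zip(fr.selected, fr.err)}
        return {
            "terms": [t.label() for t in self.terms],
            "theta": [float(v) for v in self.theta],
            "err": err_map,
            "esr": fr.esr,
            "residual_variance": float(self.residual_variance),
            "n_selected": fr.n,
            "refit": self.refit,
        }


def _finalize(y, x, cs, fr, stop, offset, refit, extra_terms):
    """Assemble the final term set and coefficients, then score residuals."""
    sel_terms = [cs.terms[l] for l in fr.selected]
    if extra_terms:
        terms = list(extra_terms) + [t for t in sel_terms
                                     if t not in set(extra_terms)]
    else:
        terms = sel_terms
    final_cs = CandidateSet(terms=terms, p=cs.p, q=cs.q, degree=cs.degree)
    Phi, target = build_design(y, x, final_cs, offset=offset)
    if refit or extra_terms:
        theta, *_ = np.linalg.lstsq(Phi, target, rcond=None)
    else:
        theta = fr.theta
    residuals = target - Phi @ theta
    resid_var = float(residuals @ residuals / residuals.size)
    return NARXModel(
        candidate_set=cs, frols=fr, terms=terms, theta=theta,
        residuals=residuals, residual_variance=resid_var,
        offset=offset, refit=bool(refit or extra_terms),
    )


def fit_nar(y, p: int, stop: StopRule | None = None, degree: int = 2,
            refit: bool = True, offset: int | None = None) -> NARXModel:
    """Fit a univariate NAR model; residual_variance is var(Y|Y-)."""
    cs = build_candidates(p, 0, degree)
    if offset is None:
        offset = cs.max_lag
    Phi, target = build_design(y, None, cs, offset=offset)
    fr = frols(target, Phi, stop)
    return _finalize(y, None, cs, fr, stop, offset, refit, None)


def fit_narx(y, x, p: int, q: int, stop: StopRule | None = None,
             degree: int = 2, refit: bool = True, offset: int | None = None,
             extra_terms: list[ModelTerm] | None = None) -> NARXModel:
    """Fit the bivariate model; residual_variance is var(Y|Y-,X-).

    ``extra_terms`` are force-included in the final least-squares refit
    (used to nest a restricted model inside the full one so the variance
    comparison is monotone).
    """
    y = np.asarray(y, dtype=float).ravel()
    x = np.asarray(x, dtype=float).ravel()
    if y.size != x.size:
        raise ValueError(f"length mismatch: y has {y.size}, x has {x.size}")
    cs = build_candidates(p, q, degree)
    if offset is None:
        offset = cs.max_lag
    Phi, target = build_design(y, x, cs, offset=offset)
    fr = frols(target, Phi, stop)
    return _finalize(y, x, cs, fr, stop, offset, refit, extra_terms)


def predict(model: NARXModel, y, x=None) -> np.ndarray:
    """One-step-ahead predictions from measured lagged values.

    Returns a full-length array; the first ``model.offset`` samples are
    NaN (insufficient history).
    """
    y = np.asarray(y, dtype=float).ravel()
    if x is not None:
        x = np.asarray(x, dtype=float).ravel()
        if x.size != y.size:
            raise ValueError(f"length mismatch: y has {y.size}, x has {x.size}")
    elif any(t.uses_input for t in model.terms):
        raise ValueError("model uses input terms but no x series given")
    final_cs = CandidateSet(terms=model.terms, p=model.candidate_set.p,
                            q=model.candidate_set.q,
                            degree=model.candidate_set.degree)
    Phi, _ = build_design(y, x, final_cs, offset=model.offset)
    out = np.full(y.size, np.nan)
    out[model.offset:] = Phi @ model.theta
    return out
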