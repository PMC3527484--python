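"""PCA factor structures, varimax rotation, forced-choice templates.

Components come from the eigendecomposition of the correlation matrix
(SPSS-style PCA): loadings are eigenvectors scaled by sqrt(eigenvalue),
percent variance is eigenvalue / n_variables. Retention follows the Kaiser
criterion (eigenvalue > 1) unless a component count is forced, mirroring
confirmatory runs. Templates for structure matching are forced-choice:
every variable goes to the factor with its largest absolute loading, so the
template partitions the variable universe the way a community detector does.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Union

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.multivariate.factor_rotation import rotate_factors

from traitnet.correlation_network import CorrelationTable
from traitnet.scale_data import ScaleDataError, ScoreMatrix


class FactorAnalysisError(ValueError):
    """Raised for degenerate inputs to the factor-analytic routines."""


@dataclass(frozen=True)
class LoadingMatrix:
    """Variables x components loading matrix with retention bookkeeping.

    ``eigenvalues`` are the pre-rotation eigenvalues of the retained
    components; ``pct_variance`` is eigenvalue / n_variables * 100 and is
    invariant under orthogonal rotation in total.
    """

    variables: tuple[str, ...]
    loadings: np.ndarray  # (n_variables, n_components)
    eigenvalues: np.ndarray  # (n_components,)
    n_variables_total: int
    rotated: bool = False

    def __post_init__(self) -> None:
        L = np.asarray(self.loadings, dtype=float)
        ev = np.asarray(self.eigenvalues, dtype=float)
        if L.shape != (len(self.variables), ev.size):
            raise FactorAnalysisError("loading matrix shape mismatch")
        if ev.size > len(self.variables):
            raise FactorAnalysisError("more components than variables")
        if not self.rotated and np.any(np.diff(ev) > 1e-10):
            raise FactorAnalysisError("eigenvalues must be non-increasing")
        object.__setattr__(self, "loadings", L)
        object.__setattr__(self, "eigenvalues", ev)

    @property
    def n_components(self) -> int:
        return self.eigenvalues.size

    @property
    def pct_variance(self) -> np.ndarray:
        """Percent of total variance per retained component (pre-rotation)."""
        return 100.0 * self.eigenvalues / self.n_variables_total

    @property
    def total_pct_variance(self) -> float:
        return float(self.pct_variance.sum())

    @property
    def communalities(self) -> np.ndarray:
        return (self.loadings**2).sum(axis=1)

    def component_labels(self) -> tuple[str, ...]:
        return tuple(f"F{k + 1}" for k in range(self.n_components))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.loadings, index=list(self.variables), columns=list(self.component_labels())
        )


@dataclass(frozen=True)
class MembershipTemplate:
    """Forced-choice variable -> factor assignment over a variable universe."""

    assignment: Mapping[str, str]
    factors: tuple[str, ...]
    below_cutoff: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        object.__setattr__(self, "assignment", dict(self.assignment))
        unknown = {f for f in self.assignment.values() if f not in self.factors}
        if unknown:
            raise FactorAnalysisError(f"assignment uses unlisted factors: {sorted(unknown)}")

    @property
    def variables(self) -> tuple[str, ...]:
        return tuple(self.assignment)

    def members(self, factor: str) -> frozenset[str]:
        return frozenset(v for v, f in self.assignment.items() if f == factor)

    def sizes(self) -> dict[str, int]:
        return {f: len(self.members(f)) for f in self.factors}

    @classmethod
    def from_mapping(cls, assignment: Mapping[str, str]) -> "MembershipTemplate":
        seen: dict[str, None] = {}
        for f in assignment.values():
            seen.setdefault(f, None)
        return cls(dict(assignment), tuple(seen))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "variable": list(self.assignment),
                "factor": list(self.assignment.values()),
                "below_cutoff": [v in self.below_cutoff for v in self.assignment],
            }
        )


def _standardize(scores: ScoreMatrix) -> np.ndarray:
    X = np.asarray(scores.scores, dtype=float)
    sd = X.std(axis=0, ddof=1)
    flat = np.where(sd == 0)[0]
    if flat.size:
        names = [scores.variables[i] for i in flat]
        raise FactorAnalysisError(f"constant (zero-variance) columns: {names}")
    return (X - X.mean(axis=0)) / sd


def pca_loadings(
    scores: ScoreMatrix, n_components: Union[int, str] = "kaiser"
) -> LoadingMatrix:
    """Unrotated PCA loadings from the correlation matrix.

    ``n_components`` is either an explicit count (a confirmatory run) or
    ``"kaiser"``: retain components with eigenvalue > 1. Column signs are
    fixed so each component's largest-magnitude loading is positive.
    """
    if scores.n_variables < 2:
        raise FactorAnalysisError("need at least 2 variables")
    if scores.n_subjects <= 2:
        raise FactorAnalysisError("need more than 2 subjects")
    X = _standardize(scores)
    R = np.corrcoef(X, rowvar=False)
    evals, evecs = np.linalg.eigh(R)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    evals = np.clip(evals, 0.0, None)

    if n_components == "kaiser":
        k = int((evals > 1.0).sum())
        if k == 0:
            raise FactorAnalysisError("no eigenvalue exceeds 1; nothing to retain")
        near = np.abs(evals - 1.0) < 0.05
        if near.any():
            warnings.warn(
                "eigenvalues near the Kaiser cutoff of 1; retention count is unstable",
                stacklevel=2,
            )
    else:
        k = int(n_components)
        if not 1 <= k <= scores.n_variables:
            raise FactorAnalysisError(f"n_components {k} out of range")
    L = evecs[:, :k] * np.sqrt(evals[:k])
    # Sign convention: largest |loading| in each column is positive.
    flip = np.sign(L[np.abs(L).argmax(axis=0), np.arange(k)])
    flip[flip == 0] = 1.0
    L = L * flip
    return LoadingMatrix(
        variables=scores.variables,
        loadings=L,
        eigenvalues=evals[:k],
        n_variables_total=scores.n_variables,
    )


def varimax_rotate(
    lm: LoadingMatrix, normalize: bool = True, tol: float = 1e-10
) -> LoadingMatrix:
    """Orthogonal varimax rotation of a loading matrix.

    With ``normalize`` (the SPSS default) rows are scaled to unit communality
    before rotation and scaled back after. Row communalities are preserved to
    numerical tolerance; a single retained component is returned unchanged
    with a warning.
    """
    if lm.n_components < 2:
        warnings.warn("varimax is a no-op for a single component", stacklevel=2)
        return lm
    L = lm.loadings.copy()
    comm = np.sqrt((L**2).sum(axis=1))
    if normalize:
        safe = np.where(comm > 0, comm, 1.0)
        L = L / safe[:, None]
    Lrot, T = rotate_factors(L, "varimax", tol=tol)
    if normalize:
        Lrot = Lrot * np.where(comm > 0, comm, 1.0)[:, None]
    if not np.allclose(T.T @ T, np.eye(T.shape[1]), atol=1e-8):
        raise FactorAnalysisError("varimax produced a non-orthogonal rotation matrix")
    flip = np.sign(Lrot[np.abs(Lrot).argmax(axis=0), np.arange(Lrot.shape[1])])
    flip[flip == 0] = 1.0
    Lrot = Lrot * flip
    # Keep component order stable by sum-of-squared-loadings, descending.
    ss = (Lrot**2).sum(axis=0)
    order = np.argsort(ss)[::-1]
    return LoadingMatrix(
        variables=lm.variables,
        loadings=Lrot[:, order],
        eigenvalues=lm.eigenvalues,
        n_variables_total=lm.n_variables_total,
        rotated=True,
    )


def forced_choice_template(
    lm: LoadingMatrix, cutoff: float = 0.40
) -> MembershipTemplate:
    """Assign every variable to the factor with its largest absolute loading.

    The cutoff does not exclude anything — templates must cover the whole
    variable universe to be comparable with a forced-choice community
    partition — it only flags variables whose best |loading| falls below it.
    Exact ties go to the lowest factor index, with a warning.
    """
    labels = lm.component_labels()
    assignment: dict[str, str] = {}
    below: set[str] = set()
    tied: list[str] = []
    absL = np.abs(lm.loadings)
    for i, var in enumerate(lm.variables):
        best = absL[i].max()
        winners = np.where(absL[i] == best)[0]
        if winners.size > 1:
            tied.append(var)
        assignment[var] = labels[int(winners[0])]
        if best < cutoff:
            below.add(var)
    if tied:
        warnings.warn(
            f"exact |loading| ties broken toward the lowest factor index: {tied}",
            stacklevel=2,
        )
    return MembershipTemplate(assignment, labels, frozenset(below))


def component_scores(
    scores: ScoreMatrix, template: MembershipTemplate
) -> ScoreMatrix:
    """Factor score = per-subject mean of the factor's member variables."""
    frame = scores.to_frame()
    missing = [v for v in template.variables if v not in frame.columns]
    if missing:
        raise FactorAnalysisError(f"template variables absent from scores: {missing}")
    cols = {}
    for factor in template.factors:
        members = sorted(template.members(factor))
        if not members:
            raise FactorAnalysisError(f"factor {factor!r} has no member variables")
        cols[factor] = frame[members].mean(axis=1).to_numpy()
    return ScoreMatrix(scores.subjects, tuple(cols), np.column_stack(list(cols.values())))


def _as_corr_matrix(correlations: Union[CorrelationTable, np.ndarray]) -> np.ndarray:
    if isinstance(correlations, CorrelationTable):
        return correlations.r
    R = np.asarray(correlations, dtype=float)
    if R.ndim != 2 or R.shape[0] != R.shape[1]:
        raise FactorAnalysisError("correlation matrix must be square")
    return R


def kmo(correlations: Union[CorrelationTable, np.ndarray]) -> float:
    """Kaiser-Meyer-Olkin measure of sampling adequacy.

    KMO = sum(r^2) / (sum(r^2) + sum(q^2)) over off-diagonal entries, where q
    are the anti-image partial correlations obtained from the inverse
    correlation matrix. Values near 1 indicate compact factor structure;
    near 0.5, diffuse correlations.
    """
    R = _as_corr_matrix(correlations)
    try:
        Rinv = np.linalg.inv(R)
    except np.linalg.LinAlgError as exc:
        raise FactorAnalysisError(
            "correlation matrix is singular; consider dropping collinear "
            "variables or ridge-regularizing"
        ) from exc
    if not np.isfinite(Rinv).all() or np.linalg.cond(R) > 1e12:
        raise FactorAnalysisError(
            "correlation matrix is numerically singular; consider regularization"
        )
    d = np.sqrt(np.diag(Rinv))
    Q = -Rinv / np.outer(d, d)
    off = ~np.eye(R.shape[0], dtype=bool)
    r2 = (R[off] ** 2).sum()
    q2 = (Q[off] ** 2).sum()
    return float(r2 / (r2 + q2))


def bartlett_sphericity(
    correlations: Union[CorrelationTable, np.ndarray], n_subjects: int
) -> tuple[float, int, float]:
    """Bartlett's test that the correlation matrix is the identity.

    chi2 = -(n - 1 - (2v + 5)/6) * ln det(R), df = v(v-1)/2, upper-tail p.
    """
    R = _as_corr_matrix(correlations)
    v = R.shape[0]
    sign, logdet = np.linalg.slogdet(R)
    if sign <= 0:
        raise FactorAnalysisError("correlation matrix has non-positive determinant")
    chi2 = -(n_subjects - 1 - (2 * v + 5) / 6.0) * logdet
    df = v * (v - 1) // 2
    p = float(stats.chi2.sf(chi2, df))
    return float(chi2), int(df), p
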