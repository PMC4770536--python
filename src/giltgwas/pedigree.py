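"""Pedigree relationship matrix and REML animal-model variance components.

The additive (numerator) relationship matrix A is built by the tabular
method; REML variance components for the animal model

    y = Xb + Za + e,   a ~ N(0, A sigma2_a),   e ~ N(0, I sigma2_e)

are estimated by EM-REML.  Because every phenotyped animal carries a
single record, the model is reduced to its marginal form on the
phenotyped subset, V = A_obs*sigma2_a + I*sigma2_e, and iterated in the
eigenbasis of A_obs, which makes each EM step O(n) after a single
eigendecomposition.  The resulting (sigma2_a, sigma2_e, h2) serve as
priors for the Bayesian whole-genome regression.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

UNKNOWN_PARENT = "0"


class PedigreeCycleError(ValueError):
    """An individual appears among its own ancestors."""


class RemlError(RuntimeError):
    """REML failed to converge or received degenerate input."""

    def __init__(self, message, last: "VarianceComponents | None" = None):
        super().__init__(message)
        self.last = last


@dataclass
class Pedigree:
    """Pedigree records (id, sire, dam); ``"0"`` or None marks an unknown parent."""

    ids: list
    sires: list
    dams: list

    def __post_init__(self):
        self.ids = [str(i) for i in self.ids]
        self.sires = [self._norm(p) for p in self.sires]
        self.dams = [self._norm(p) for p in self.dams]
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate ids in pedigree")
        if not (len(self.ids) == len(self.sires) == len(self.dams)):
            raise ValueError("ids, sires, dams must have equal length")

    @staticmethod
    def _norm(p):
        p = None if p is None else str(p)
        return None if p in (None, UNKNOWN_PARENT, "", "nan") else p

    def __len__(self) -> int:
        return len(self.ids)

    def records(self):
        """Iterate (id, sire, dam) triples with None for unknown parents."""
        return zip(self.ids, self.sires, self.dams)

    def topological_order(self) -> list:
        """Ids ordered parents-before-offspring; raises on a cycle, naming an id."""
        parents = {
            i: [p for p in (s, d) if p is not None]
            for i, s, d in self.records()
        }
        order: list = []
        state: dict = {}  # 0 = visiting, 1 = done

        for root in self.ids:
            if root in state:
                continue
            stack = [(root, iter(parents.get(root, ())))]
            state[root] = 0
            while stack:
                node, it = stack[-1]
                advanced = False
                for p in it:
                    if p not in parents:
                        continue  # parent outside the recorded pedigree
                    if state.get(p) == 0:
                        raise PedigreeCycleError(
                            f"individual {p!r} appears among its own ancestors"
                        )
                    if p not in state:
                        state[p] = 0
                        stack.append((p, iter(parents.get(p, ()))))
                        advanced = True
                        break
                if not advanced:
                    stack.pop()
                    state[node] = 1
                    order.append(node)
        return order

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Pedigree":
        return cls(
            ids=df["id"].tolist(), sires=df["sire"].tolist(), dams=df["dam"].tolist()
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": self.ids,
                "sire": [s or UNKNOWN_PARENT for s in self.sires],
                "dam": [d or UNKNOWN_PARENT for d in self.dams],
            }
        )


@dataclass
class RelationshipMatrix:
    """Numerator relationship matrix with the id ordering of its rows."""

    values: np.ndarray
    ids: list

    def index_of(self, wanted) -> np.ndarray:
        pos = {a: i for i, a in enumerate(self.ids)}
        try:
            return np.array([pos[str(w)] for w in wanted], dtype=int)
        except KeyError as e:  # pragma: no cover - message clarity
            raise KeyError(f"id {e.args[0]!r} not in relationship matrix") from e

    def submatrix(self, wanted) -> np.ndarray:
        ix = self.index_of(wanted)
        return self.values[np.ix_(ix, ix)]


@dataclass
class VarianceComponents:
    """Animal-model variance components (days^2) and heritability."""

    sigma2_a: float
    sigma2_e: float
    se_h2: float | None = None
    n_iter: int = 0
    loglik_path: list = field(default_factory=list)
    #: approximate sampling covariance of (sigma2_a, sigma2_e) from the
    #: average-information matrix, when available
    cov: object = None

    @property
    def h2(self) -> float:
        tot = self.sigma2_a + self.sigma2_e
        return self.sigma2_a / tot if tot > 0 else 0.0

    @property
    def total(self) -> float:
        return self.sigma2_a + self.sigma2_e


@dataclass
class PriorSpec:
    """Scaled-inverse-chi-square priors for the Gibbs sampler variances."""

    nu_u: float
    s_u: float
    nu_e: float
    s_e: float


def build_amatrix(ped: Pedigree) -> RelationshipMatrix:
    """Numerator relationship matrix by the tabular method.

    Founders get diagonal 1; A_ii = 1 + 0.5*A(sire, dam) (0 if a parent is
    unknown); A_ij = 0.5*(A(j, sire_i) + A(j, dam_i)) for previously
    processed j.  Parents outside the recorded pedigree are treated as
    unknown founders.
    """
    order = ped.topological_order()
    pos = {a: i for i, a in enumerate(order)}
    known = set(ped.ids)
    par = {i: (s, d) for i, s, d in ped.records()}
    n = len(order)
    A = np.zeros((n, n))
    for a in order:
        i = pos[a]
        s, d = par[a]
        si = pos[s] if (s in known) else None
        di = pos[d] if (d in known) else None
        row = np.zeros(i)
        if si is not None:
            row += 0.5 * A[si, :i]
        if di is not None:
            row += 0.5 * A[di, :i]
        A[i, :i] = row
        A[:i, i] = row
        A[i, i] = 1.0 + (0.5 * A[si, di] if (si is not None and di is not None) else 0.0)
    return RelationshipMatrix(values=A, ids=order)


def _design_from_classes(labels) -> np.ndarray:
    """Full-rank fixed-effect design: intercept + dummies dropping the first class."""
    labels = pd.Series(labels).astype(str)
    classes = list(pd.unique(labels))
    X = np.ones((len(labels), len(classes)))
    for j, c in enumerate(classes[1:], start=1):
        X[:, j] = (labels == c).to_numpy(float)
    return X


def reml_fit(
    phen: pd.DataFrame,
    A: RelationshipMatrix,
    fixed: str = "year_season",
    max_iter: int = 5000,
    tol: float = 1e-5,
    start_h2: float = 0.5,
) -> VarianceComponents:
    """EM-REML variance components for the animal model.

    Parameters
    ----------
    phen : DataFrame with ``animal_id``, ``age_days`` and the fixed-effect
        class column named by ``fixed`` (or ``fixed=None`` for intercept only).
    A : relationship matrix covering every phenotyped animal.

    Raises :class:`RemlError` (carrying the last iterate) on
    non-convergence, and on degenerate input (fewer than 2 records).
    """
    y = phen["age_days"].to_numpy(float)
    n = y.size
    if n < 2:
        raise RemlError("need at least 2 phenotyped animals")
    X = (
        _design_from_classes(phen[fixed])
        if fixed is not None and fixed in phen.columns
        else np.ones((n, 1))
    )
    p = X.shape[1]
    if n - p < 2:
        raise RemlError("not enough residual degrees of freedom")
    A_obs = A.submatrix(phen["animal_id"].tolist())

    d, U = np.linalg.eigh(A_obs)
    d = np.clip(d, 0.0, None)
    yt = U.T @ y
    Xt = U.T @ X

    vary = float(np.var(y, ddof=1))
    sa = max(start_h2 * vary, 1e-8)
    se = max((1.0 - start_h2) * vary, 1e-8)

    def _quantities(sa, se):
        w = 1.0 / (sa * d + se)
        XtW = Xt * w[:, None]
        XtWX = Xt.T @ XtW
        cf = np.linalg.cholesky(XtWX)
        beta = np.linalg.solve(XtWX, XtW.T @ yt)
        Py = w * (yt - Xt @ beta)
        # log restricted likelihood (constant dropped)
        ll = -0.5 * (
            np.sum(np.log(sa * d + se))
            + 2.0 * np.sum(np.log(np.diag(cf)))
            + float(yt @ Py)
        )
        def trPV(v):  # tr(P diag(v))
            t1 = np.sum(w * v)
            M = Xt.T @ (Xt * (w * w * v)[:, None])
            t2 = np.trace(np.linalg.solve(XtWX, M))
            return t1 - t2
        return Py, ll, trPV

    ll_prev = -np.inf
    path = []
    for it in range(1, max_iter + 1):
        Py, ll, trPV = _quantities(sa, se)
        path.append(ll)
        if not np.isfinite(ll):
            raise RemlError(
                "restricted likelihood diverged",
                last=VarianceComponents(sa, se, n_iter=it, loglik_path=path),
            )
        if it > 1 and abs(ll - ll_prev) < tol:
            break
        ll_prev = ll
        # EM updates: sigma2_new = sigma2 + sigma2^2/n * (y'P V P y - tr(P V))
        sa_new = sa + (sa * sa / n) * (float((Py * d) @ Py) - trPV(d))
        se_new = se + (se * se / n) * (float(Py @ Py) - trPV(np.ones(n)))
        sa, se = max(sa_new, 1e-10), max(se_new, 1e-10)
    else:
        raise RemlError(
            f"EM-REML did not converge in {max_iter} iterations",
            last=VarianceComponents(sa, se, n_iter=max_iter, loglik_path=path),
        )

    # approximate SE of h2: average-information on (sigma2_a, sigma2_e), delta method
    Py, _, _ = _quantities(sa, se)
    w = 1.0 / (sa * d + se)
    XtW = Xt * w[:, None]
    XtWX = Xt.T @ XtW

    def Pv(v):  # P @ v in the rotated basis
        return w * v - XtW @ np.linalg.solve(XtWX, XtW.T @ v)

    PdPy = Pv(d * Py)
    PPy = Pv(Py)
    AI = 0.5 * np.array(
        [
            [float((d * Py) @ PdPy), float((d * Py) @ PPy)],
            [float((d * Py) @ PPy), float(Py @ PPy)],
        ]
    )
    se_h2 = None
    cov = None
    try:
        cov = np.linalg.inv(AI)
        tot = sa + se
        grad = np.array([se, -sa]) / (tot * tot)
        v = float(grad @ cov @ grad)
        if v >= 0:
            se_h2 = float(np.sqrt(v))
    except np.linalg.LinAlgError:
        pass
    return VarianceComponents(
        sigma2_a=float(sa),
        sigma2_e=float(se),
        se_h2=se_h2,
        n_iter=len(path),
        loglik_path=path,
        cov=cov,
    )


def variance_priors(
    vc: VarianceComponents,
    m_snps: int,
    pi: float,
    mean_het: float,
    nu_u: float = 4.0,
    nu_e: float = 10.0,
) -> PriorSpec:
    """Scaled-inverse-chi-square prior scales from REML variance components.

    The per-SNP effect-variance scale S_u is set so that the prior mean of
    the total marker variance, m*(1-pi)*mean_het*E[sigma2_u], equals the
    REML additive variance; the residual scale so that E[sigma2_e] equals
    the REML residual variance (E[X] = S*nu/(nu-2) for a scaled-inv-chi2).

    ``mean_het`` is the average heterozygosity 2p(1-p) over retained SNPs.
    """
    if not 0 <= pi < 1:
        raise ValueError("pi must lie in [0, 1); pi = 1 leaves no SNP variance")
    if mean_het <= 0 or m_snps < 1:
        raise ValueError("mean_het must be > 0 and m_snps >= 1")
    if nu_u <= 2 or nu_e <= 2:
        raise ValueError("prior degrees of freedom must exceed 2 for a finite mean")
    e_sigma2_u = vc.sigma2_a / (m_snps * (1.0 - pi) * mean_het)
    s_u = e_sigma2_u * (nu_u - 2.0) / nu_u
    s_e = vc.sigma2_e * (nu_e - 2.0) / nu_e
    return PriorSpec(nu_u=float(nu_u), s_u=float(s_u), nu_e=float(nu_e), s_e=float(s_e))
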