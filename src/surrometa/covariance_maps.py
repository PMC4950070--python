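"""Maps between natural and product-normal parameterisations of the
between-study covariance.

A multivariate random-effects meta-analysis places a covariance matrix
``T`` (``T[j,k] = tau_j * tau_k * rho_jk``) on the vector of true
treatment effects.  The same distribution can be written as a chain of
univariate conditional normals ("product-normal formulation"): the first
effect is ``N(eta1, psi_1^2)`` and each subsequent effect ``j`` is
normal with mean ``lambda_j0 + sum_k lambda_jk mu_k`` over its declared
parents ``k < j`` and conditional variance ``psi_j^2``.  Three
structures are supported:

``unstructured``
    every effect conditions on all of its predecessors; the chain is an
    exact reparameterisation of any positive-definite ``T``.
``sequential``
    each effect conditions only on its immediate predecessor; the
    non-adjacent correlations are then forced to be products along the
    chain (``rho_13 = rho_12 * rho_23`` in three dimensions), i.e. the
    off-tridiagonal entries of the precision matrix ``T^-1`` are zero.
``custom``
    an arbitrary parent set per effect (child conditions only on lower
    indices), which zeroes exactly the declared conditional
    independences.

The slopes are the multivariate-normal regression coefficients of a
child on its parents and the conditional variances are the exact Schur
complements, so the chain's marginal covariance reproduces ``T``
entry-for-entry for every modelled correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "BetweenParams",
    "ConditionalParams",
    "parents_for_structure",
    "between_to_conditional",
    "conditional_to_between",
    "implied_covariance",
]

_PRODUCT_RULE_TOL = 1e-8


def parents_for_structure(
    n: int, structure: str, adjacency: list[list[int]] | None = None
) -> list[list[int]]:
    """Return the parent set (0-based indices) of each outcome.

    ``adjacency``, required for ``structure='custom'``, lists the parent
    set of each outcome; parents must have lower indices than the child.
    """
    if structure == "unstructured":
        return [list(range(j)) for j in range(n)]
    if structure == "sequential":
        return [[] if j == 0 else [j - 1] for j in range(n)]
    if structure == "custom":
        if adjacency is None:
            raise ValueError("custom structure requires an adjacency list")
        if len(adjacency) != n:
            raise ValueError(f"adjacency must list parents for all {n} outcomes")
        out = []
        for j, pa in enumerate(adjacency):
            pa = sorted(int(p) for p in pa)
            if any(p < 0 or p >= j for p in pa):
                raise ValueError(
                    f"outcome {j}: parents {pa} must be earlier outcomes"
                )
            out.append(pa)
        return out
    raise ValueError(f"unknown structure {structure!r}")


@dataclass
class BetweenParams:
    """Natural between-study parameters: SDs ``tau`` and correlations ``rho``.

    ``rho`` is an ``N x N`` symmetric matrix with unit diagonal.  For
    ``sequential`` / ``custom`` structures, entries for non-modelled
    pairs may be ``nan``; they are filled with the values implied by the
    conditional-independence structure.
    """

    tau: np.ndarray
    rho: np.ndarray
    structure: str = "unstructured"
    adjacency: list[list[int]] | None = None

    def __post_init__(self) -> None:
        self.tau = np.asarray(self.tau, dtype=float)
        self.rho = np.asarray(self.rho, dtype=float)
        n = self.tau.size
        if self.rho.shape != (n, n):
            raise ValueError("rho must be N x N")
        if np.any(self.tau <= 0):
            raise ValueError("between-study SDs must be positive")
        with np.errstate(invalid="ignore"):
            if not np.allclose(self.rho, self.rho.T, equal_nan=True):
                raise ValueError("rho must be symmetric")
        if not np.allclose(np.diag(self.rho), 1.0):
            raise ValueError("rho must have unit diagonal")
        off = self.rho[~np.eye(n, dtype=bool)]
        off = off[np.isfinite(off)]
        if off.size and (np.any(off <= -1) or np.any(off >= 1)):
            raise ValueError("correlations must lie in (-1, 1)")

    @property
    def n(self) -> int:
        return self.tau.size

    def parents(self) -> list[list[int]]:
        return parents_for_structure(self.n, self.structure, self.adjacency)

    def to_dict(self) -> dict:
        return {
            "tau": self.tau.tolist(),
            "rho": self.rho.tolist(),
            "structure": self.structure,
            "adjacency": self.adjacency,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BetweenParams":
        return cls(
            tau=np.asarray(d["tau"], dtype=float),
            rho=np.asarray(d["rho"], dtype=float),
            structure=d.get("structure", "unstructured"),
            adjacency=d.get("adjacency"),
        )


@dataclass
class ConditionalParams:
    """Product-normal chain parameters.

    ``slopes[j]`` holds the regression coefficients of outcome ``j`` on
    its parents (aligned with ``parents[j]``); ``psi`` are the
    conditional SDs.  ``eta1`` and the intercepts ``lambda0`` are free
    location parameters (not determined by ``tau``/``rho``) and default
    to zero.
    """

    psi: np.ndarray
    slopes: list[np.ndarray]
    parents: list[list[int]] = field(default_factory=list)
    structure: str = "unstructured"
    eta1: float = 0.0
    lambda0: np.ndarray | None = None  # intercepts for outcomes 2..N

    def __post_init__(self) -> None:
        self.psi = np.asarray(self.psi, dtype=float)
        self.slopes = [np.asarray(s, dtype=float) for s in self.slopes]
        n = self.psi.size
        if len(self.slopes) != n:
            raise ValueError("need one slope vector per outcome")
        if not self.parents:
            self.parents = parents_for_structure(n, self.structure)
        for j, (s, pa) in enumerate(zip(self.slopes, self.parents)):
            if s.size != len(pa):
                raise ValueError(f"outcome {j}: {s.size} slopes for {len(pa)} parents")
        if np.any(self.psi <= 0):
            raise ValueError("conditional SDs psi must be positive")
        if self.lambda0 is None:
            self.lambda0 = np.zeros(max(n - 1, 0))
        else:
            self.lambda0 = np.asarray(self.lambda0, dtype=float)

    @property
    def n(self) -> int:
        return self.psi.size

    def pooled_effects(self) -> np.ndarray:
        """Marginal means beta_j implied by eta1, the intercepts and slopes."""
        beta = np.empty(self.n)
        beta[0] = self.eta1
        for j in range(1, self.n):
            beta[j] = self.lambda0[j - 1] + self.slopes[j] @ beta[self.parents[j]]
        return beta

    def to_dict(self) -> dict:
        return {
            "psi": self.psi.tolist(),
            "slopes": [s.tolist() for s in self.slopes],
            "parents": self.parents,
            "structure": self.structure,
            "eta1": self.eta1,
            "lambda0": self.lambda0.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ConditionalParams":
        return cls(
            psi=np.asarray(d["psi"], dtype=float),
            slopes=[np.asarray(s, dtype=float) for s in d["slopes"]],
            parents=[list(p) for p in d["parents"]],
            structure=d.get("structure", "unstructured"),
            eta1=float(d.get("eta1", 0.0)),
            lambda0=np.asarray(d["lambda0"], dtype=float) if "lambda0" in d else None,
        )


def implied_covariance(b: BetweenParams) -> tuple[np.ndarray, bool]:
    """Covariance matrix ``T`` implied by (tau, rho) and a PD flag.

    Missing (``nan``) correlations are first filled with the values
    implied by the declared conditional-independence structure.
    """
    rho = _fill_missing_rho(b)
    T = np.outer(b.tau, b.tau) * rho
    pd = bool(np.linalg.eigvalsh(T).min() > 0)
    return T, pd


def _fill_missing_rho(b: BetweenParams) -> np.ndarray:
    rho = b.rho.copy()
    if not np.isnan(rho).any():
        return rho
    if b.structure == "unstructured":
        raise ValueError("unstructured rho may not contain missing entries")
    parents = b.parents()
    modelled = np.eye(b.n, dtype=bool)
    for j, pa in enumerate(parents):
        for p in pa:
            modelled[j, p] = modelled[p, j] = True
    if np.isnan(rho[modelled]).any():
        raise ValueError("modelled correlations may not be missing")
    # run the chain on the modelled entries only to recover the implied full rho
    tmp = BetweenParams(b.tau, np.where(modelled, rho, np.nan), b.structure, b.adjacency)
    c = between_to_conditional(tmp)
    C = _chain_covariance(c)
    full = C / np.outer(b.tau, b.tau)
    np.fill_diagonal(full, 1.0)
    out = np.where(np.isnan(rho), full, rho)
    mismatch = np.abs(out - full) > 1e-6
    if mismatch.any():
        j, k = np.argwhere(mismatch)[0]
        raise ValueError(
            f"correlation rho[{j},{k}]={out[j, k]:.6f} contradicts the declared "
            f"structure (implied {full[j, k]:.6f}); use the unstructured or a "
            "custom structure instead"
        )
    return out


def between_to_conditional(
    b: BetweenParams, legacy_psi: bool = False
) -> ConditionalParams:
    """Slopes and conditional SDs of the product-normal chain matching ``b``.

    Slopes are the regression coefficients of each effect on its
    declared parents and ``psi_j^2`` the exact conditional
    (Schur-complement) variance, so that the chain reproduces ``T`` for
    every modelled correlation.  ``eta1`` and the intercepts are free
    parameters and are returned as zero.

    ``legacy_psi`` switches to the literal textbook cascade
    ``psi_j^2 = tau_j^2 - sum_k lambda_jk^2 tau_k^2`` which drops the
    parent cross-covariance terms; it is provided for audit only and is
    *not* consistent with the chain's marginal covariance when parents
    are correlated.
    """
    parents = b.parents()
    n = b.n
    rho = b.rho
    # Build the modelled covariance targets; for sequential/custom we only
    # ever read modelled (parent-child) entries plus implied parent blocks.
    C = np.zeros((n, n))  # implied chain covariance, filled as we go
    slopes: list[np.ndarray] = []
    psi2 = np.empty(n)
    for j in range(n):
        pa = parents[j]
        if not pa:
            slopes.append(np.zeros(0))
            psi2[j] = b.tau[j] ** 2
            C[j, j] = psi2[j]
            continue
        cov_pj = np.array(
            [b.tau[p] * b.tau[j] * rho[p, j] for p in pa], dtype=float
        )
        if np.isnan(cov_pj).any():
            raise ValueError(f"modelled correlation missing for outcome {j}")
        Spp = C[np.ix_(pa, pa)]
        try:
            lam = np.linalg.solve(Spp, cov_pj)
        except np.linalg.LinAlgError as exc:
            raise ValueError("parent covariance block is singular") from exc
        if legacy_psi:
            p2 = b.tau[j] ** 2 - np.sum(lam**2 * b.tau[np.array(pa)] ** 2)
        else:
            p2 = b.tau[j] ** 2 - lam @ cov_pj
        if p2 <= 0:
            raise ValueError(
                f"implied covariance not positive definite: psi_{j + 1}^2 = "
                f"{p2:.6g} <= 0 for tau={b.tau.tolist()}, structure "
                f"{b.structure!r}"
            )
        slopes.append(lam)
        psi2[j] = p2
        # propagate covariance down the chain
        C[j, :j] = lam @ C[np.ix_(pa, range(j))]
        C[:j, j] = C[j, :j]
        C[j, j] = (b.tau[j] ** 2) if not legacy_psi else (p2 + lam @ Spp @ lam)
    if b.structure == "unstructured" and np.isnan(rho).any():
        raise ValueError("unstructured rho may not contain missing entries")
    if b.structure in ("sequential", "custom"):
        # declared non-modelled correlations must match the implied ones
        full = C / np.outer(b.tau, b.tau)
        declared = ~np.isnan(rho)
        bad = declared & (np.abs(np.where(declared, rho, 0) - np.where(declared, full, 0)) > 1e-6)
        np.fill_diagonal(bad, False)
        if bad.any():
            j, k = np.argwhere(bad)[0]
            raise ValueError(
                f"rho[{j},{k}]={rho[j, k]:.6f} violates the "
                f"{b.structure} structure (implies {full[j, k]:.6f}, e.g. the "
                "product rule rho_13 = rho_12*rho_23); use the unstructured "
                "or a custom structure"
            )
    return ConditionalParams(
        psi=np.sqrt(psi2),
        slopes=slopes,
        parents=parents,
        structure=b.structure,
    )


def _chain_covariance(c: ConditionalParams) -> np.ndarray:
    """Marginal covariance of the product-normal chain, by forward propagation."""
    n = c.n
    C = np.zeros((n, n))
    for j in range(n):
        pa = c.parents[j]
        lam = c.slopes[j]
        if pa:
            C[j, :j] = lam @ C[np.ix_(pa, range(j))]
            C[:j, j] = C[j, :j]
            C[j, j] = c.psi[j] ** 2 + lam @ C[np.ix_(pa, pa)] @ lam
        else:
            C[j, j] = c.psi[j] ** 2
    return C


def conditional_to_between(c: ConditionalParams) -> BetweenParams:
    """Exact inverse of :func:`between_to_conditional`.

    Propagates variances and covariances down the chain and reads off
    ``tau`` and ``rho``; round-trips with the forward map to ~1e-10.
    """
    C = _chain_covariance(c)
    tau = np.sqrt(np.diag(C))
    rho = C / np.outer(tau, tau)
    np.fill_diagonal(rho, 1.0)
    adjacency = c.parents if c.structure == "custom" else None
    return BetweenParams(tau=tau, rho=rho, structure=c.structure, adjacency=adjacency)
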