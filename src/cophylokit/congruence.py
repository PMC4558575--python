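"""Distance-based host-parasite congruence testing (ParaFit-style).

The global test asks whether host and parasite evolutionary distances
are independent given the observed association links.  Both distance
matrices are embedded in Euclidean space by principal coordinates
analysis; with host coordinates B, parasite coordinates C and the binary
association matrix A (parasites x hosts), the fourth-corner matrix
D4 = C' A B summarizes host-parasite covariation and the global statistic
is the sum of its squared entries.  Significance comes from permuting
the host identities (rows of B); each link's own contribution is the
drop in the global statistic when that link is removed, tested under the
same permutation scheme.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .trees import DistanceMatrix, HostParasiteLinks

__all__ = [
    "PrincipalCoordinates",
    "CongruenceResult",
    "pcoa",
    "parafit_global",
    "parafit_links",
]


@dataclass
class PrincipalCoordinates:
    """Euclidean embedding of a distance matrix."""

    labels: list[str]
    coordinates: np.ndarray  # taxa x axes
    eigenvalues: np.ndarray  # per retained axis, decreasing

    @property
    def n_axes(self) -> int:
        return self.coordinates.shape[1]


@dataclass
class CongruenceResult:
    """Outcome of a ParaFit-style congruence test."""

    global_stat: float
    global_p: float | None
    n_permutations: int
    seed: int | None
    link_labels: list[tuple[str, str]] = field(default_factory=list)
    link_stats: list[float] = field(default_factory=list)
    link_p: list[float] = field(default_factory=list)

    def links_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "parasite": [p for p, _ in self.link_labels],
                "host": [h for _, h in self.link_labels],
                "stat": self.link_stats,
                "p": self.link_p,
            }
        )

    def n_significant_links(self, alpha: float = 0.05) -> int:
        return int(sum(p <= alpha for p in self.link_p))


def pcoa(D: DistanceMatrix, correction: str | None = None) -> PrincipalCoordinates:
    """Principal coordinates of a distance matrix.

    The squared distances are double-centered (Gower), eigendecomposed,
    and axes with eigenvalue > 1e-10 * max eigenvalue are retained and
    scaled by the square root of their eigenvalue.  Negative eigenvalues
    are dropped by default; ``correction="cailliez"`` adds the Cailliez
    constant to off-diagonal distances first, making the matrix
    Euclidean.
    """
    d = np.asarray(D.values, dtype=float)
    if not np.allclose(d, d.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    n = d.shape[0]
    if correction == "cailliez":
        d = d + _cailliez_constant(d) * (1 - np.eye(n))
    elif correction is not None:
        raise ValueError(f"unknown correction {correction!r}")
    J = np.eye(n) - np.ones((n, n)) / n
    G = -0.5 * J @ (d**2) @ J
    eigval, eigvec = np.linalg.eigh((G + G.T) / 2)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    if eigval.size and eigval[0] > 0:
        keep = eigval > 1e-10 * eigval[0]
    else:
        keep = np.zeros_like(eigval, dtype=bool)
    eigval, eigvec = eigval[keep], eigvec[:, keep]
    coords = eigvec * np.sqrt(eigval)
    return PrincipalCoordinates(list(D.labels), coords, eigval)


def _cailliez_constant(d: np.ndarray) -> float:
    """Smallest constant whose addition makes the matrix Euclidean."""
    n = d.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    delta1 = -0.5 * J @ (d**2) @ J
    delta2 = -0.5 * J @ d @ J
    upper = np.block([[np.zeros((n, n)), 2 * delta1], [-np.eye(n), -4 * delta2]])
    c = float(np.max(np.real(np.linalg.eigvals(upper))))
    return max(c, 0.0)


def _parafit_setup(host_D, parasite_D, links):
    if len(links.host_labels) < 3 or len(links.parasite_labels) < 3:
        raise ValueError("need at least 3 hosts and 3 parasites")
    missing_h = set(links.host_labels) - set(host_D.labels)
    missing_p = set(links.parasite_labels) - set(parasite_D.labels)
    if missing_h or missing_p:
        raise ValueError(
            f"labels missing from distance matrices: hosts {sorted(missing_h)}, "
            f"parasites {sorted(missing_p)}"
        )
    B = pcoa(host_D.submatrix(links.host_labels)).coordinates
    Cc = pcoa(parasite_D.submatrix(links.parasite_labels)).coordinates
    A = links.matrix.astype(float)
    return B, Cc, A


def _global_stat(Cc, A, B) -> float:
    D4 = Cc.T @ A @ B
    return float(np.sum(D4**2))


def parafit_global(
    host_D: DistanceMatrix,
    parasite_D: DistanceMatrix,
    links: HostParasiteLinks,
    n_perm: int = 9999,
    seed=None,
) -> CongruenceResult:
    """Global test of independence between host and parasite distances.

    p = (1 + #{permuted stat >= observed}) / (1 + n_perm), permuting
    host identities.
    """
    B, Cc, A = _parafit_setup(host_D, parasite_D, links)
    rng = np.random.default_rng(seed)
    M = Cc.T @ A  # constant across permutations
    obs = float(np.sum((M @ B) ** 2))
    n_ge = 0
    for _ in range(n_perm):
        perm = rng.permutation(B.shape[0])
        if float(np.sum((M @ B[perm]) ** 2)) >= obs:
            n_ge += 1
    return CongruenceResult(
        global_stat=obs,
        global_p=(1 + n_ge) / (1 + n_perm),
        n_permutations=n_perm,
        seed=seed,
    )


def parafit_links(
    host_D: DistanceMatrix,
    parasite_D: DistanceMatrix,
    links: HostParasiteLinks,
    n_perm: int = 9999,
    seed=None,
) -> CongruenceResult:
    """Global plus per-link congruence test.

    Each link's statistic is the global statistic minus the global
    statistic with that link removed; the same host permutations supply
    the per-link null distributions.
    """
    B, Cc, A = _parafit_setup(host_D, parasite_D, links)
    rng = np.random.default_rng(seed)
    pairs = [
        (i, j)
        for i in range(A.shape[0])
        for j in range(A.shape[1])
        if A[i, j]
    ]

    def link_stats(Bmat):
        g = _global_stat(Cc, A, Bmat)
        out = np.empty(len(pairs))
        for k, (i, j) in enumerate(pairs):
            A[i, j] = 0.0
            out[k] = g - _global_stat(Cc, A, Bmat)
            A[i, j] = 1.0
        return g, out

    obs_global, obs_links = link_stats(B)
    n_ge_global = 0
    n_ge_links = np.zeros(len(pairs), dtype=int)
    for _ in range(n_perm):
        perm = rng.permutation(B.shape[0])
        g, s = link_stats(B[perm])
        if g >= obs_global:
            n_ge_global += 1
        n_ge_links += s >= obs_links
    labels = [
        (links.parasite_labels[i], links.host_labels[j]) for i, j in pairs
    ]
    return CongruenceResult(
        global_stat=obs_global,
        global_p=(1 + n_ge_global) / (1 + n_perm),
        n_permutations=n_perm,
        seed=seed,
        link_labels=labels,
        link_stats=obs_links.tolist(),
        link_p=((1 + n_ge_links) / (1 + n_perm)).tolist(),
    )
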