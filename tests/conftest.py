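"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from ensdyn import GeneratorSpec, gen_linear_ensemble, make_toy_chain

SEED = 0  # canonical seed for derandomized statistical tests


@pytest.fixture(scope="session")
def planted_ensemble():
    """Reference planted-mode ensemble: amps (3, 1) Å, σ = 0.05 Å, n = 500."""
    spec = GeneratorSpec(seed=SEED, n_residues=50, n_conformers=500,
                         mode_amplitudes=(3.0, 1.0), noise_sigma=0.05)
    return gen_linear_ensemble(spec)


@pytest.fixture(scope="session")
def toy_chain():
    return make_toy_chain(10)


# ---------------------------------------------------------------------------
# Independent oracles (deliberately naive; never share code with the package)
# ---------------------------------------------------------------------------

def euler_rotation(a: float, b: float, c: float) -> np.ndarray:
    """Rotation from intrinsic x-y-z Euler angles."""
    ca, sa = np.cos(a), np.sin(a)
    cb, sb = np.cos(b), np.sin(b)
    cc, sc = np.cos(c), np.sin(c)
    Rx = np.array([[1, 0, 0], [0, ca, -sa], [0, sa, ca]])
    Ry = np.array([[cb, 0, sb], [0, 1, 0], [-sb, 0, cb]])
    Rz = np.array([[cc, -sc, 0], [sc, cc, 0], [0, 0, 1]])
    return Rz @ Ry @ Rx


def _batch_euler(angles: np.ndarray) -> np.ndarray:
    """(K, 3) Euler angle triples -> (K, 3, 3) rotation matrices (vectorized)."""
    a, b, c = angles[:, 0], angles[:, 1], angles[:, 2]
    ca, sa = np.cos(a), np.sin(a)
    cb, sb = np.cos(b), np.sin(b)
    cc, sc = np.cos(c), np.sin(c)
    K = len(angles)
    R = np.empty((K, 3, 3))
    # Rz(c) @ Ry(b) @ Rx(a), expanded
    R[:, 0, 0] = cc * cb
    R[:, 0, 1] = cc * sb * sa - sc * ca
    R[:, 0, 2] = cc * sb * ca + sc * sa
    R[:, 1, 0] = sc * cb
    R[:, 1, 1] = sc * sb * sa + cc * ca
    R[:, 1, 2] = sc * sb * ca - cc * sa
    R[:, 2, 0] = -sb
    R[:, 2, 1] = cb * sa
    R[:, 2, 2] = cb * ca
    return R


def _batch_rmsd(mc: np.ndarray, rc: np.ndarray, R: np.ndarray) -> np.ndarray:
    rotated = np.einsum("kij,nj->kni", R, mc)
    return np.sqrt(np.mean(np.sum((rotated - rc) ** 2, axis=2), axis=1))


def grid_search_rmsd(mobile: np.ndarray, reference: np.ndarray,
                     coarse_n: int = 17, n_starts: int = 30,
                     levels: int = 18, local_n: int = 7) -> float:
    """Brute-force minimum RMSd over rotations via an Euler-angle grid.

    Translation is optimal in closed form (centroid alignment) for any fixed
    rotation.  A dense coarse scan over the full angle ranges seeds
    ``n_starts`` local grid refinements, each shrinking the search width
    threefold per level; multi-start protects against basin capture.
    """
    mc = mobile - mobile.mean(axis=0)
    rc = reference - reference.mean(axis=0)
    grid = np.linspace(-np.pi, np.pi, coarse_n)
    coarse = np.array(np.meshgrid(grid, grid, grid)).reshape(3, -1).T
    vals = _batch_rmsd(mc, rc, _batch_euler(coarse))
    seeds = coarse[np.argsort(vals)[:n_starts]]
    best = float(vals.min())
    for center in seeds:
        width = 2 * np.pi / (coarse_n - 1)
        center = center.copy()
        for _ in range(levels):
            axes = [np.linspace(center[k] - width, center[k] + width, local_n)
                    for k in range(3)]
            local = np.array(np.meshgrid(*axes)).reshape(3, -1).T
            lv = _batch_rmsd(mc, rc, _batch_euler(local))
            i = int(np.argmin(lv))
            if lv[i] < best:
                best = float(lv[i])
            center = local[i]
            # halve (not third) so a minimum at the box edge stays inside
            width /= 2.0
    return best


def naive_average_linkage(dist: np.ndarray, n_clusters: int) -> list[set[int]]:
    """Exhaustive O(F³) agglomerative average-linkage (UPGMA) clustering.

    Cluster–cluster distance is the mean of all member-pair distances from
    the original matrix; at each step the closest pair of clusters merges.
    """
    clusters: list[set[int]] = [{i} for i in range(len(dist))]
    while len(clusters) > n_clusters:
        best = (np.inf, None)
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                d = np.mean([dist[a, b] for a in clusters[i]
                             for b in clusters[j]])
                if d < best[0]:
                    best = (d, (i, j))
        i, j = best[1]
        clusters[i] = clusters[i] | clusters[j]
        del clusters[j]
    return clusters


def partition_from_labels(labels: np.ndarray) -> set[frozenset]:
    return {frozenset(np.nonzero(labels == c)[0].tolist())
            for c in set(labels.tolist())}
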