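"""Independent reference implementations used only to cross-check the
package: a quaternion-eigenvalue superposition RMSD (Horn's method, a
different algorithm from the SVD route used in the library) and a microstate
enumeration of the two-site + ISRIB linkage partition function."""

import numpy as np


def quaternion_superposition_rmsd(p: np.ndarray, q: np.ndarray) -> float:
    """Optimal rigid-superposition RMSD via the largest eigenvalue of Horn's
    4x4 quaternion matrix."""
    p = np.asarray(p, float)
    q = np.asarray(q, float)
    pc = p - p.mean(axis=0)
    qc = q - q.mean(axis=0)
    s = pc.T @ qc
    sxx, sxy, sxz = s[0]
    syx, syy, syz = s[1]
    szx, szy, szz = s[2]
    k = np.array([
        [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
        [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
        [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
        [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz],
    ])
    lam_max = float(np.linalg.eigvalsh(k)[-1])
    gp = float((pc**2).sum())
    gq = float((qc**2).sum())
    return float(np.sqrt(max(gp + gq - 2.0 * lam_max, 0.0) / len(p)))


def enumerate_linkage_populations(params, isrib_nM: float, alphaP_uM: float) -> dict:
    """Brute-force microstate enumeration of the linkage partition function.

    The two αP sites are treated as distinguishable microscopic sites with
    intrinsic constant K_P1; double occupancy carries the extra factor
    (K_P2/K_P1)·c_P. Summing the 2x2x2 microstates must reproduce the
    macroscopic weights (including the statistical factor 2)."""
    kappa = params.k_p1_per_uM
    omega = (params.k_p2_per_uM / params.k_p1_per_uM) * params.c_p
    coupling = {0: 1.0, 1: params.g1, 2: params.g2}
    acc: dict[tuple[int, int], float] = {}
    for site1 in (0, 1):
        for site2 in (0, 1):
            for i in (0, 1):
                j = site1 + site2
                w = (kappa * alphaP_uM) ** j
                if j == 2:
                    w *= omega
                if i == 1:
                    w *= params.k_isrib_per_nM * isrib_nM * coupling[j]
                acc[(i, j)] = acc.get((i, j), 0.0) + w
    z = sum(acc.values())
    return {k: v / z for k, v in acc.items()}
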