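"""Independent brute-force oracles used only by the test suite."""

import numpy as np


def quaternion_superposition_rmsd(mobile: np.ndarray, reference: np.ndarray) -> float:
    """Minimum RMSD by Horn's closed-form quaternion method.

    Independent of the package's SVD-based superposition: builds the 4x4
    quaternion key matrix and reads the optimal RMSD off its largest
    eigenvalue.
    """
    x = mobile - mobile.mean(axis=0)
    y = reference - reference.mean(axis=0)
    s = x.T @ y
    sxx, sxy, sxz = s[0]
    syx, syy, syz = s[1]
    szx, szy, szz = s[2]
    key = np.array(
        [
            [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
            [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
            [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
            [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz],
        ]
    )
    lam = np.linalg.eigvalsh(key)[-1]
    msd = (np.sum(x**2) + np.sum(y**2) - 2.0 * lam) / len(x)
    return float(np.sqrt(max(msd, 0.0)))


def brute_force_contacts(a: np.ndarray, b: np.ndarray, cutoff: float) -> int:
    """O(N^2) double loop counting pairs strictly under the cutoff."""
    count = 0
    for p in a:
        for q in b:
            if np.sqrt(np.sum((p - q) ** 2)) < cutoff:
                count += 1
    return count


def random_rigid_transform(rng: np.random.Generator):
    """A uniformly random proper rotation and a random translation."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    rot = np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )
    return rot, rng.uniform(-50, 50, size=3)
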