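import numpy as np
import pytest

from ndqkit import synthetic_data as sd


@pytest.fixture
def two_state_scheme():
    """Two intermediates with lifetimes separated 100x (M-like and O-like)."""
    return sd.PhotocycleScheme(
        intermediate_names=("M", "O"),
        lifetimes=(1e-3, 1e-1),
        band_centers=(400.0, 620.0),
        band_widths=(25.0, 35.0),
        band_amplitudes=(0.8, 1.0),
        ground_center=535.5,
        ground_width=40.0,
        ground_amplitude=1.0,
    )


@pytest.fixture
def sequence_family():
    """60-sequence aligned family with planted motif and subgroup letters."""
    records, labels = sd.generate_sequence_family(
        n_per_class={"Subgroup1": 30, "Subgroup2": 30},
        mutation_rate=0.02,
        gap_rate=0.0,
        seed=11,
    )
    return records, labels


def quaternion_rmsd(P: np.ndarray, Q: np.ndarray) -> float:
    """Independent RMSD oracle via the quaternion characteristic method.

    Builds the 4x4 key matrix from the covariance of the centered point
    sets; the optimal superposition RMSD follows from its largest
    eigenvalue without ever forming the rotation matrix.
    """
    P = P - P.mean(axis=0)
    Q = Q - Q.mean(axis=0)
    M = P.T @ Q
    Sxx, Sxy, Sxz = M[0]
    Syx, Syy, Syz = M[1]
    Szx, Szy, Szz = M[2]
    K = np.array(
        [
            [Sxx + Syy + Szz, Syz - Szy, Szx - Sxz, Sxy - Syx],
            [Syz - Szy, Sxx - Syy - Szz, Sxy + Syx, Szx + Sxz],
            [Szx - Sxz, Sxy + Syx, -Sxx + Syy - Szz, Syz + Szy],
            [Sxy - Syx, Szx + Sxz, Syz + Szy, -Sxx - Syy + Szz],
        ]
    )
    lam = np.linalg.eigvalsh(K).max()
    n = P.shape[0]
    msd = max((np.sum(P**2) + np.sum(Q**2) - 2.0 * lam) / n, 0.0)
    return float(np.sqrt(msd))
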