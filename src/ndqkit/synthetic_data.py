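"""Seeded generators for every stage of the pipeline.

Each generator emulates the statistical structure one analysis stage assumes,
so the whole pipeline is testable offline:

* sequential-photocycle ΔA(t, λ) surfaces — a first-order unidirectional
  chain A1 → A2 → ... → An → ground with Gaussian difference bands and
  additive Gaussian noise on a combined linear/log time base;
* two-pKa Henderson–Hasselbalch titration curves and Hill saturation curves;
* aligned sequence families with planted motif residues and subgroup letters
  (ground-truth labels emitted alongside);
* rigid-body-perturbed toy structures for superposition metrics.

All randomness flows through one ``numpy.random.Generator`` seeded per call;
identical (config, seed) gives bit-identical output.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg

from .kinetics_lda import TransientDataset
from .titration_fits import TitrationCurve
from .structure_metrics import Atom, StructureModel

__all__ = [
    "PhotocycleScheme",
    "SimulationConfig",
    "ernar_scheme",
    "mixed_time_grid",
    "chain_concentrations",
    "simulate_transient_dataset",
    "simulate_titration_curve",
    "simulate_hill_curve",
    "generate_sequence_family",
    "generate_toy_structure_pair",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class PhotocycleScheme:
    """A sequential photocycle: intermediates, lifetimes, and their bands.

    ``lifetimes[i]`` is the time constant (s) of the decay of intermediate i
    into intermediate i+1 (the last one decays to the ground state).  Each
    intermediate absorbs as a Gaussian band; the parent (ground) state band
    is subtracted to form the difference spectrum.
    """

    intermediate_names: tuple[str, ...]
    lifetimes: tuple[float, ...]
    band_centers: tuple[float, ...]
    band_widths: tuple[float, ...]
    band_amplitudes: tuple[float, ...]
    ground_center: float
    ground_width: float
    ground_amplitude: float

    def __post_init__(self):
        n = len(self.intermediate_names)
        for name, vals in (
            ("lifetimes", self.lifetimes),
            ("band_centers", self.band_centers),
            ("band_widths", self.band_widths),
            ("band_amplitudes", self.band_amplitudes),
        ):
            if len(vals) != n:
                raise ValueError(f"{name} must have one entry per intermediate")
        if any(tau <= 0 for tau in self.lifetimes):
            raise ValueError("lifetimes must be strictly positive")
        if any(b >= a for a, b in zip(self.lifetimes[1:], self.lifetimes)):
            raise ValueError("lifetimes must be strictly increasing along the chain")
        if any(w <= 0 for w in self.band_widths) or self.ground_width <= 0:
            raise ValueError("band widths must be positive")


def ernar_scheme() -> PhotocycleScheme:
    """Default five-step scheme mimicking the sodium-pumping photocycle.

    K1 forms in ps, decays in the early microseconds to K2; the blue-shifted
    M intermediate appears around 1 ms; the red-shifted O states rise within
    a few ms and the ground state recovers on the seconds timescale.
    """
    return PhotocycleScheme(
        intermediate_names=("K1", "K2", "M", "O1", "O2"),
        lifetimes=(2e-12, 7e-6, 1e-3, 5e-3, 6.0),
        band_centers=(590.0, 590.0, 400.0, 620.0, 620.0),
        band_widths=(30.0, 30.0, 25.0, 35.0, 35.0),
        band_amplitudes=(1.0, 1.0, 0.8, 1.0, 1.0),
        ground_center=535.5,
        ground_width=40.0,
        ground_amplitude=1.0,
    )


@dataclass(frozen=True)
class SimulationConfig:
    """Noise, seed, and the sampling grids of a simulated measurement.

    ``time_grid`` is (linear_segment_end, points_per_decade, start, end) in
    seconds: the linear segment from ``start`` to ``linear_segment_end`` is
    sampled with ``points_per_decade`` evenly spaced points, then the log
    segment continues to ``end`` at ``points_per_decade`` points per decade.
    ``wavelength_grid`` is (start, end, step) in nm.
    """

    seed: int = 0
    noise_sigma: float = 0.0
    time_grid: tuple[float, int, float, float] = (1e-6, 20, 1e-7, 10.0)
    wavelength_grid: tuple[float, float, float] = (330.0, 700.0, 10.0)

    def __post_init__(self):
        lin_end, ppd, start, end = self.time_grid
        if not (start < end and start < lin_end <= end):
            raise ValueError("invalid time grid ordering")
        if ppd < 2:
            raise ValueError("points_per_decade must be >= 2")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        w0, w1, dw = self.wavelength_grid
        if not (w0 < w1 and dw > 0):
            raise ValueError("invalid wavelength grid")


def mixed_time_grid(linear_end: float, points_per_decade: int, start: float, end: float) -> np.ndarray:
    """Linear sampling up to ``linear_end``, then log points-per-decade."""
    lin = np.linspace(start, linear_end, points_per_decade, endpoint=False)
    n_log = max(2, int(np.ceil(np.log10(end / linear_end) * points_per_decade)) + 1)
    log = np.geomspace(linear_end, end, n_log)
    t = np.unique(np.concatenate([lin, log]))
    return t[(t >= start) & (t <= end)]


def chain_concentrations(
    lifetimes: np.ndarray, times: np.ndarray, method: str = "bateman"
) -> np.ndarray:
    """Intermediate populations of a first-order chain, c[time, state].

    The chain is A1 -> A2 -> ... -> An -> ground with c1(0) = 1 and rate
    constants k_i = 1/tau_i.  ``method='bateman'`` uses the closed-form
    Bateman solution (requires distinct lifetimes); ``method='expm'`` uses
    the matrix exponential and tolerates degenerate lifetimes.
    """
    taus = np.asarray(lifetimes, dtype=float)
    times = np.asarray(times, dtype=float)
    k = 1.0 / taus
    n = len(taus)
    if method == "bateman":
        for i, j in itertools.combinations(range(n), 2):
            if abs(taus[i] - taus[j]) <= 1e-9 * max(taus[i], taus[j]):
                raise ValueError(
                    "duplicate lifetimes make the Bateman denominators degenerate; "
                    "use method='expm'"
                )
        c = np.zeros((times.size, n))
        for m in range(n):
            pref = np.prod(k[:m])  # product of the first m rates
            acc = np.zeros(times.size)
            for i in range(m + 1):
                denom = np.prod([k[j] - k[i] for j in range(m + 1) if j != i])
                acc += np.exp(-k[i] * times) / denom
            c[:, m] = pref * acc
        return c
    elif method == "expm":
        K = np.diag(-k)
        for i in range(1, n):
            K[i, i - 1] = k[i - 1]
        c = np.empty((times.size, n))
        for it, t in enumerate(times):
            c[it] = scipy.linalg.expm(K * t)[:, 0]
        return c
    raise ValueError(f"unknown method {method!r}")


def _gaussian_band(wl, center, width, amplitude):
    return amplitude * np.exp(-((wl - center) ** 2) / (2.0 * width**2))


def simulate_transient_dataset(
    scheme: PhotocycleScheme, config: SimulationConfig, method: str = "bateman"
) -> TransientDataset:
    """Simulate a flash-photolysis ΔA(t, λ) surface for a sequential chain.

    ΔA(t, λ) = sum_i c_i(t) [S_i(λ) - S_ground(λ)] + Gaussian noise, so the
    signal relaxes to zero as the chain empties back into the ground state.
    Mass is conserved: sum_i c_i + c_ground = 1 at every time.
    """
    lin_end, ppd, t0, t1 = config.time_grid
    times = mixed_time_grid(lin_end, ppd, t0, t1)
    w0, w1, dw = config.wavelength_grid
    wavelengths = np.arange(w0, w1 + 0.5 * dw, dw)
    c = chain_concentrations(np.array(scheme.lifetimes), times, method=method)
    s_ground = _gaussian_band(wavelengths, scheme.ground_center, scheme.ground_width, scheme.ground_amplitude)
    diff = np.stack(
        [
            _gaussian_band(wavelengths, ctr, wid, amp) - s_ground
            for ctr, wid, amp in zip(scheme.band_centers, scheme.band_widths, scheme.band_amplitudes)
        ]
    )  # [state, wavelength]
    delta_A = c @ diff
    rng = np.random.default_rng(config.seed)
    if config.noise_sigma > 0:
        delta_A = delta_A + rng.normal(0.0, config.noise_sigma, delta_A.shape)
    return TransientDataset(
        times=times,
        wavelengths=wavelengths,
        delta_A=delta_A,
        metadata={
            "seed": config.seed,
            "noise_sigma": config.noise_sigma,
            "intermediates": list(scheme.intermediate_names),
            "lifetimes_s": list(scheme.lifetimes),
        },
    )


def simulate_titration_curve(
    pka_values,
    amplitudes,
    baseline: float,
    ph_grid,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> TitrationCurve:
    """y(pH) = baseline + sum_k A_k / (1 + 10^(pH - pKa_k)) + noise.

    Each term is a Henderson–Hasselbalch transition contributing its full
    amplitude at low pH (protonated side) and vanishing at high pH.
    """
    ph = np.asarray(ph_grid, dtype=float)
    if ph.size == 0:
        raise ValueError("empty pH grid")
    pka = np.asarray(pka_values, dtype=float)
    amp = np.asarray(amplitudes, dtype=float)
    if not np.all(np.isfinite(pka)):
        raise ValueError("pKa values must be finite")
    y = baseline + np.sum(amp[:, None] / (1.0 + 10.0 ** (ph[None, :] - pka[:, None])), axis=0)
    if noise_sigma > 0:
        y = y + np.random.default_rng(seed).normal(0.0, noise_sigma, y.shape)
    return TitrationCurve(pH=ph, observable=y, observable_kind="synthetic")


def simulate_hill_curve(
    K_half: float,
    n_hill: float,
    y_max: float,
    conc_grid,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Hill saturation table: y = y_max c^n / (K^n + c^n) + noise."""
    if K_half <= 0 or n_hill <= 0:
        raise ValueError("K_half and n_hill must be positive")
    c = np.asarray(conc_grid, dtype=float)
    if np.any(c < 0):
        raise ValueError("negative concentrations")
    with np.errstate(divide="ignore", invalid="ignore"):
        y = np.where(c > 0, y_max * c**n_hill / (K_half**n_hill + c**n_hill), 0.0)
    if noise_sigma > 0:
        y = y + np.random.default_rng(seed).normal(0.0, noise_sigma, y.shape)
    return pd.DataFrame({"concentration_mM": c, "amplitude": y})


DEFAULT_SCAFFOLD_LENGTH = 280


def _random_scaffold(length: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


def generate_sequence_family(
    scaffold: str | None = None,
    motif_positions: tuple[int, ...] = (109, 112, 116, 123, 251, 216),
    motif_residues: str = "RNDQDK",
    subgroup_position: int = 74,
    subgroup_letters: dict[str, str] | None = None,
    n_per_class: dict[str, int] | None = None,
    mutation_rate: float = 0.02,
    gap_rate: float = 0.0,
    seed: int = 0,
) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Aligned family with planted motif residues and subgroup letters.

    Positions are 1-based on the ungapped scaffold; the alignment is the
    scaffold frame itself (gaps are single-column deletions), so planted
    columns map one-to-one to scaffold positions.  Mutations and gaps never
    touch planted columns.  Returns (records, labels): records as (id, row)
    pairs with a gapless reference named ``REF`` first, and a DataFrame with
    the ground-truth subgroup label per generated sequence.
    """
    rng = np.random.default_rng(seed)
    if scaffold is None:
        scaffold = _random_scaffold(DEFAULT_SCAFFOLD_LENGTH, rng)
    if subgroup_letters is None:
        subgroup_letters = {"Subgroup1": "L", "Subgroup2": "E"}
    if n_per_class is None:
        n_per_class = {"Subgroup1": 10, "Subgroup2": 10}
    if not (0 <= mutation_rate <= 1 and 0 <= gap_rate <= 1):
        raise ValueError("rates must lie in [0, 1]")
    planted = set(motif_positions) | {subgroup_position}
    if len(planted) != len(motif_positions) + 1:
        raise ValueError("overlapping planted positions")
    if max(planted) > len(scaffold):
        raise ValueError("planted position beyond scaffold length")

    base = list(scaffold)
    for pos, aa in zip(motif_positions, motif_residues):
        base[pos - 1] = aa

    records: list[tuple[str, str]] = [("REF", "".join(base))]
    rows = []
    for label in sorted(n_per_class):
        letter = subgroup_letters[label]
        for i in range(n_per_class[label]):
            seq = base.copy()
            seq[subgroup_position - 1] = letter
            for col in range(len(seq)):
                if (col + 1) in planted:
                    continue
                u = rng.random()
                if u < gap_rate:
                    seq[col] = "-"
                elif u < gap_rate + mutation_rate:
                    choices = AMINO_ACIDS.replace(seq[col], "")
                    seq[col] = choices[rng.integers(len(choices))]
            rid = f"{label}_{i:03d}"
            records.append((rid, "".join(seq)))
            rows.append({"id": rid, "subgroup": label, "subgroup_letter": letter})
    labels = pd.DataFrame(rows)
    return records, labels


def generate_toy_structure_pair(
    n_atoms: int,
    rotation: np.ndarray | None = None,
    translation: np.ndarray | None = None,
    per_atom_jitter_sigma: float = 0.0,
    seed: int = 0,
) -> tuple[StructureModel, StructureModel]:
    """A random CA trace and its rigid transform plus optional jitter."""
    if n_atoms < 3:
        raise ValueError("need at least 3 atoms")
    rng = np.random.default_rng(seed)
    if rotation is None:
        rotation = np.eye(3)
    rotation = np.asarray(rotation, dtype=float)
    if not np.isclose(np.linalg.det(rotation), 1.0, atol=1e-8):
        raise ValueError("rotation must be proper (det = +1)")
    if translation is None:
        translation = np.zeros(3)
    translation = np.asarray(translation, dtype=float)
    xyz = rng.normal(0.0, 5.0, (n_atoms, 3))
    xyz2 = xyz @ rotation.T + translation
    if per_atom_jitter_sigma > 0:
        xyz2 = xyz2 + rng.normal(0.0, per_atom_jitter_sigma, xyz2.shape)

    def to_model(coords):
        atoms = [
            Atom(
                chain="A",
                res_number=i + 1,
                res_name="ALA",
                atom_name="CA",
                element="C",
                x=float(c[0]),
                y=float(c[1]),
                z=float(c[2]),
                occupancy=1.0,
                alt_loc="",
            )
            for i, c in enumerate(coords)
        ]
        return StructureModel(atoms=atoms, source_format="synthetic")

    return to_model(xyz), to_model(xyz2)
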