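"""Synthetic three-group cohort generator.

Emulates the post-preprocessing state of a structural + resting-state fMRI
study of MCI-to-AD conversion: each subject carries 68-region
Desikan-Killiany morphometry (cortical thickness / volume / surface area)
and a 90-region AAL BOLD-like time series filtered into three low-frequency
bands (full 0.01-0.08 Hz, slow-4 0.027-0.08 Hz, slow-5 0.01-0.027 Hz,
TR = 3 s).

Group differences are *planted*: a standardized mean shift on chosen
(region, measure) morphometry slots, and an additive perturbation of the
latent inter-regional correlation on chosen node sets.  The latent signal is
multivariate Gaussian over a small-world backbone, so its correlation matrix
is directly controllable; band-limited series are obtained by zero-phase
Butterworth filtering, which leaves inter-regional correlations intact.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
from scipy import signal

from .atlases import N_AAL, N_DK

GROUPS = ("MCInc", "MCIc", "AD")

#: (low Hz, high Hz) of the three analysis bands.
BANDS: dict[str, tuple[float, float]] = {
    "full": (0.01, 0.08),
    "slow4": (0.027, 0.08),
    "slow5": (0.01, 0.027),
}

MEASURES = ("thickness", "volume", "area")

# Morphometry marginals: thickness in mm, volume/area lognormal (mm^3/mm^2).
_THICKNESS_MEAN = 2.5
_THICKNESS_SD = 0.25
_THICKNESS_FLOOR = 0.5
_LOG_VOLUME_MEAN = 7.8   # exp(7.8) ~ 2440 mm^3
_LOG_AREA_MEAN = 6.9     # exp(6.9) ~ 992 mm^2
_LOG_SCALE_SD = 0.25


class ConfigurationError(ValueError):
    """Raised when a cohort configuration violates its invariants."""


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for one synthetic cohort.

    Parameters
    ----------
    n_per_group
        Subjects per diagnostic group.  Defaults mirror a typical
        MCInc/MCIc/AD conversion cohort (55/30/19).
    n_timepoints
        fMRI volumes retained per subject after discarding the
        stabilization scans.
    tr_seconds
        Sampling interval of the BOLD series.
    struct_effect
        ``group -> {(region_index, measure): shift}`` with ``region_index``
        0-based into the Desikan-Killiany ordering and ``shift`` a
        standardized mean shift (units of the measure's between-subject SD;
        applied on the log scale for volume/area).
    conn_effect
        ``group -> [(node_tuple, delta), ...]``: every unordered pair within
        ``node_tuple`` (0-based AAL indices) has ``delta`` added to its
        latent correlation for that group.
    base_corr
        Latent correlation placed on backbone edges shared by all groups.
    noise_sd
        SD of white measurement noise added to the latent series before
        filtering.
    """

    n_per_group: Mapping[str, int] = field(
        default_factory=lambda: {"MCInc": 55, "MCIc": 30, "AD": 19}
    )
    n_struct_regions: int = N_DK
    n_func_regions: int = N_AAL
    n_timepoints: int = 130
    tr_seconds: float = 3.0
    bands: Mapping[str, tuple[float, float]] = field(default_factory=lambda: dict(BANDS))
    struct_effect: Mapping[str, Mapping[tuple[int, str], float]] = field(default_factory=dict)
    conn_effect: Mapping[str, Sequence[tuple[tuple[int, ...], float]]] = field(
        default_factory=dict
    )
    base_corr: float = 0.25
    noise_sd: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if not self.n_per_group:
            raise ConfigurationError("at least one group is required")
        for g, n in self.n_per_group.items():
            if n <= 0:
                raise ConfigurationError(f"group {g!r} has non-positive size {n}")
        if self.n_timepoints < 32:
            raise ConfigurationError("n_timepoints must be at least 32")
        if self.tr_seconds <= 0:
            raise ConfigurationError("tr_seconds must be positive")
        nyquist = 0.5 / self.tr_seconds
        for name, (low, high) in self.bands.items():
            if not (0.0 < low < high < nyquist):
                raise ConfigurationError(
                    f"band {name!r} = ({low}, {high}) violates 0 < low < high < "
                    f"Nyquist ({nyquist:.4g} Hz)"
                )
        if self.noise_sd <= 0:
            raise ConfigurationError("noise_sd must be positive")
        for g, effects in self.struct_effect.items():
            for (region, measure) in effects:
                if not 0 <= region < self.n_struct_regions:
                    raise ConfigurationError(
                        f"struct_effect region {region} out of range for group {g!r}"
                    )
                if measure not in MEASURES:
                    raise ConfigurationError(f"unknown morphometry measure {measure!r}")
        for g, perturbations in self.conn_effect.items():
            for nodes, _delta in perturbations:
                for node in nodes:
                    if not 0 <= node < self.n_func_regions:
                        raise ConfigurationError(
                            f"conn_effect node {node} out of range for group {g!r}"
                        )

    def with_effects(
        self,
        struct_effect: Mapping[str, Mapping[tuple[int, str], float]] | None = None,
        conn_effect: Mapping[str, Sequence[tuple[tuple[int, ...], float]]] | None = None,
    ) -> "CohortConfig":
        kwargs = {}
        if struct_effect is not None:
            kwargs["struct_effect"] = struct_effect
        if conn_effect is not None:
            kwargs["conn_effect"] = conn_effect
        return replace(self, **kwargs)


@dataclass
class SubjectRecord:
    """One synthetic subject: group label, morphometry and band-limited series."""

    subject_id: str
    group: str
    thickness: np.ndarray
    volume: np.ndarray
    area: np.ndarray
    timeseries: dict[str, np.ndarray]

    def validate(self) -> None:
        for name, arr, n in (
            ("thickness", self.thickness, N_DK),
            ("volume", self.volume, N_DK),
            ("area", self.area, N_DK),
        ):
            if arr.shape != (n,):
                raise ValueError(f"{name} must have shape ({n},), got {arr.shape}")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} contains non-finite values")
            if np.any(arr <= 0):
                raise ValueError(f"{name} must be strictly positive")
        for band, ts in self.timeseries.items():
            if ts.ndim != 2 or ts.shape[0] != N_AAL:
                raise ValueError(
                    f"time series for band {band!r} must have {N_AAL} rows, got {ts.shape}"
                )
            if not np.all(np.isfinite(ts)):
                raise ValueError(f"time series for band {band!r} contains non-finite values")


def bandpass(series: np.ndarray, low: float, high: float, tr: float) -> np.ndarray:
    """Zero-phase 4th-order Butterworth band-pass along the last axis.

    Forward-backward filtering doubles the effective order and cancels phase
    distortion, the standard treatment of resting-state BOLD series.
    """
    series = np.asarray(series, dtype=float)
    if series.shape[-1] < 32:
        raise ValueError("need at least 32 time points to band-pass filter")
    nyquist = 0.5 / tr
    if not (0.0 < low < high):
        raise ValueError(f"require 0 < low < high, got ({low}, {high})")
    if high >= nyquist:
        raise ValueError(f"high edge {high} Hz is at or above Nyquist {nyquist:.4g} Hz")
    sos = signal.butter(4, [low, high], btype="bandpass", fs=1.0 / tr, output="sos")
    return signal.sosfiltfilt(sos, series, axis=-1)


def _backbone_adjacency(n_nodes: int, seed: int) -> np.ndarray:
    """Small-world (Watts-Strogatz) binary backbone shared by all groups."""
    graph = nx.watts_strogatz_graph(n_nodes, k=6, p=0.1, seed=seed)
    return nx.to_numpy_array(graph, nodelist=range(n_nodes), dtype=float)


def _nearest_correlation(matrix: np.ndarray, floor: float = 1e-3) -> np.ndarray:
    """Clip eigenvalues at ``floor`` and renormalize to unit diagonal."""
    sym = (matrix + matrix.T) / 2.0
    eigval, eigvec = np.linalg.eigh(sym)
    eigval = np.clip(eigval, floor, None)
    fixed = (eigvec * eigval) @ eigvec.T
    d = np.sqrt(np.diag(fixed))
    fixed = fixed / np.outer(d, d)
    np.fill_diagonal(fixed, 1.0)
    return fixed


def latent_correlation(config: CohortConfig, group: str) -> np.ndarray:
    """Target correlation matrix of the latent signal for one group."""
    n = config.n_func_regions
    adjacency = _backbone_adjacency(n, seed=config.seed % (2**31))
    corr = np.eye(n) + config.base_corr * adjacency
    for nodes, delta in config.conn_effect.get(group, ()):  # pairs within the set
        nodes = np.asarray(nodes, dtype=int)
        for a_idx in range(len(nodes)):
            for b_idx in range(a_idx + 1, len(nodes)):
                a, b = nodes[a_idx], nodes[b_idx]
                corr[a, b] += delta
                corr[b, a] += delta
    return _nearest_correlation(corr)


def _sample_morphometry(
    rng: np.random.Generator, config: CohortConfig, group: str
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    n = config.n_struct_regions
    shifts = {m: np.zeros(n) for m in MEASURES}
    for (region, measure), shift in config.struct_effect.get(group, {}).items():
        shifts[measure][region] += shift

    thickness = rng.normal(
        _THICKNESS_MEAN + shifts["thickness"] * _THICKNESS_SD, _THICKNESS_SD, size=n
    )
    thickness = np.maximum(thickness, _THICKNESS_FLOOR)
    volume = np.exp(
        rng.normal(_LOG_VOLUME_MEAN + shifts["volume"] * _LOG_SCALE_SD, _LOG_SCALE_SD, size=n)
    )
    area = np.exp(
        rng.normal(_LOG_AREA_MEAN + shifts["area"] * _LOG_SCALE_SD, _LOG_SCALE_SD, size=n)
    )
    return thickness, volume, area


def _sample_timeseries(
    rng: np.random.Generator, config: CohortConfig, chol: np.ndarray
) -> dict[str, np.ndarray]:
    n, t = config.n_func_regions, config.n_timepoints
    pad = 40  # extra samples absorb filter transients before trimming
    latent = chol @ rng.standard_normal((n, t + 2 * pad))
    latent = latent + config.noise_sd * rng.standard_normal((n, t + 2 * pad))
    out: dict[str, np.ndarray] = {}
    for band, (low, high) in config.bands.items():
        filtered = bandpass(latent, low, high, config.tr_seconds)
        out[band] = filtered[:, pad : pad + t].copy()
    return out


def default_conversion_effects(
    group: str = "MCIc", atrophy_sd: float = 1.0, conn_delta: float = -0.35
) -> tuple[dict, dict]:
    """AD-conversion-like planted effects for one group.

    Gray-matter atrophy (standardized shifts around ``atrophy_sd``) in the
    medial-temporal regions most consistently reported in conversion
    studies -- entorhinal and parahippocampal cortex bilaterally, plus
    entorhinal/inferior-temporal volume loss -- and a weakening
    (``conn_delta`` correlation units) of the latent coupling within a
    hippocampal-temporal-thalamic node set of the AAL atlas (hippocampus,
    parahippocampal gyrus, thalamus, superior temporal pole, middle
    temporal gyrus).

    Returns ``(struct_effect, conn_effect)`` mappings accepted by
    :class:`CohortConfig`.
    """
    struct_effect = {
        group: {
            (4, "thickness"): -atrophy_sd,   # entorhinal L
            (38, "thickness"): -atrophy_sd,  # entorhinal R
            (14, "thickness"): -0.8 * atrophy_sd,  # parahippocampal L
            (48, "thickness"): -0.8 * atrophy_sd,  # parahippocampal R
            (4, "volume"): -atrophy_sd,
            (7, "volume"): -0.8 * atrophy_sd,  # inferior temporal L
        }
    }
    conn_effect = {group: [((36, 37, 38, 39, 76, 77, 82, 84), conn_delta)]}
    return struct_effect, conn_effect


def generate_cohort(config: CohortConfig) -> list[SubjectRecord]:
    """Draw the full cohort; identical config (incl. seed) gives identical output."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    subjects: list[SubjectRecord] = []
    for group in config.n_per_group:
        chol = np.linalg.cholesky(latent_correlation(config, group))
        for i in range(config.n_per_group[group]):
            thickness, volume, area = _sample_morphometry(rng, config, group)
            timeseries = _sample_timeseries(rng, config, chol)
            record = SubjectRecord(
                subject_id=f"{group}_{i:03d}",
                group=group,
                thickness=thickness,
                volume=volume,
                area=area,
                timeseries=timeseries,
            )
            record.validate()
            subjects.append(record)
    return subjects
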