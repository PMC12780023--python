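"""Core containers shared across the pipeline.

The analysis operates on trial-epoched, parcellated ROI time series
(one block per participant x condition), ground-truth coupling networks
used by the synthetic generator, and the derived connectivity objects
(shifted-MI matrix pairs, per-trial NDTE matrices, condition-level
masked connectivity, flow vectors, hub search results).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

ATTENTION_LEVELS = ("active", "passive")
CUE_LEVELS = ("intensity", "spectral")
MOTION_LEVELS = ("looming", "receding", "static")


class Condition(NamedTuple):
    """Factor triple labelling one experimental cell."""

    attention: str
    cue: str
    motion: str

    def validate(self) -> "Condition":
        if self.attention not in ATTENTION_LEVELS:
            raise ValueError(
                f"unknown attention level {self.attention!r}; expected one of {ATTENTION_LEVELS}"
            )
        if self.cue not in CUE_LEVELS:
            raise ValueError(f"unknown cue level {self.cue!r}; expected one of {CUE_LEVELS}")
        if self.motion not in MOTION_LEVELS:
            raise ValueError(
                f"unknown motion level {self.motion!r}; expected one of {MOTION_LEVELS}"
            )
        return self

    def label(self) -> str:
        return f"{self.attention}-{self.cue}-{self.motion}"

    @classmethod
    def from_label(cls, label: str) -> "Condition":
        parts = label.split("-")
        if len(parts) != 3:
            raise ValueError(f"malformed condition label {label!r}")
        return cls(*parts).validate()


# The 34 cortical areas of the Desikan-Killiany atlas; crossed with both
# hemispheres this yields the default 68-ROI parcellation.
_DK_AREAS = (
    "bankssts",
    "caudalanteriorcingulate",
    "caudalmiddlefrontal",
    "cuneus",
    "entorhinal",
    "frontalpole",
    "fusiform",
    "inferiorparietal",
    "inferiortemporal",
    "insula",
    "isthmuscingulate",
    "lateraloccipital",
    "lateralorbitofrontal",
    "lingual",
    "medialorbitofrontal",
    "middletemporal",
    "paracentral",
    "parahippocampal",
    "parsopercularis",
    "parsorbitalis",
    "parstriangularis",
    "pericalcarine",
    "postcentral",
    "posteriorcingulate",
    "precentral",
    "precuneus",
    "rostralanteriorcingulate",
    "rostralmiddlefrontal",
    "superiorfrontal",
    "superiorparietal",
    "superiortemporal",
    "supramarginal",
    "temporalpole",
    "transversetemporal",
)


@dataclass(frozen=True)
class Parcellation:
    """Ordered cortical ROI labels with a hemisphere tag per ROI."""

    labels: tuple[str, ...]
    hemispheres: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.hemispheres):
            raise ValueError("labels and hemispheres must have equal length")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("ROI labels must be unique")
        bad = set(self.hemispheres) - {"L", "R"}
        if bad:
            raise ValueError(f"hemisphere tags must be 'L' or 'R', got {bad}")

    def __len__(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"ROI label {label!r} not in parcellation") from None

    @classmethod
    def desikan_killiany(cls) -> "Parcellation":
        """The 68-area cortical parcellation (34 areas x 2 hemispheres)."""
        labels = tuple(f"{h}_{a}" for h in ("L", "R") for a in _DK_AREAS)
        hemis = tuple(h for h in ("L", "R") for _ in _DK_AREAS)
        return cls(labels, hemis)

    @classmethod
    def generic(cls, n_rois: int) -> "Parcellation":
        """Anonymous parcellation for synthetic experiments of any size."""
        half = n_rois // 2
        labels = tuple(f"roi{i:02d}" for i in range(n_rois))
        hemis = tuple("L" if i < half else "R" for i in range(n_rois))
        return cls(labels, hemis)


@dataclass
class EpochedRoiSeries:
    """Trial-epoched ROI time series for one participant x condition.

    ``values`` has shape (n_trials, n_rois, n_time). ``t0`` is the time of
    the first sample in seconds relative to the event of interest (e.g. the
    distance-change onset).
    """

    values: np.ndarray
    sampling_rate: float
    t0: float
    parcellation: Parcellation
    condition: Condition | None = None
    participant_id: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("values must be a (trials, rois, time) array")
        if np.isnan(self.values).any():
            raise ValueError("epoched series contains missing values")
        if self.values.shape[1] != len(self.parcellation):
            raise ValueError(
                f"ROI axis ({self.values.shape[1]}) does not match parcellation "
                f"({len(self.parcellation)})"
            )
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")

    @property
    def n_trials(self) -> int:
        return self.values.shape[0]

    @property
    def n_rois(self) -> int:
        return self.values.shape[1]

    @property
    def n_time(self) -> int:
        return self.values.shape[2]

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds relative to the event."""
        return self.t0 + np.arange(self.n_time) / self.sampling_rate

    def replace_values(self, values: np.ndarray, t0: float | None = None) -> "EpochedRoiSeries":
        return EpochedRoiSeries(
            values=values,
            sampling_rate=self.sampling_rate,
            t0=self.t0 if t0 is None else t0,
            parcellation=self.parcellation,
            condition=self.condition,
            participant_id=self.participant_id,
        )


@dataclass
class GroundTruthNetwork:
    """Linear VAR(p) generative network used by the synthetic generator.

    ``coupling[i, j, l]`` is the influence of ROI ``j`` at lag ``l + 1``
    on ROI ``i``. Stationarity requires the companion-form spectral radius
    to be below one.
    """

    coupling: np.ndarray
    noise_sd: np.ndarray

    def __post_init__(self) -> None:
        self.coupling = np.asarray(self.coupling, dtype=float)
        if self.coupling.ndim != 3 or self.coupling.shape[0] != self.coupling.shape[1]:
            raise ValueError("coupling must have shape (n_rois, n_rois, order)")
        self.noise_sd = np.broadcast_to(
            np.asarray(self.noise_sd, dtype=float), (self.coupling.shape[0],)
        ).copy()
        if np.any(self.noise_sd <= 0):
            raise ValueError("noise_sd must be positive for every ROI")

    @property
    def n_rois(self) -> int:
        return self.coupling.shape[0]

    @property
    def order(self) -> int:
        return self.coupling.shape[2]

    def companion_matrix(self) -> np.ndarray:
        n, p = self.n_rois, self.order
        comp = np.zeros((n * p, n * p))
        # top block row is [A_1 ... A_p]
        for lag in range(p):
            comp[:n, lag * n : (lag + 1) * n] = self.coupling[:, :, lag]
        if p > 1:
            comp[n:, : n * (p - 1)] = np.eye(n * (p - 1))
        return comp

    def spectral_radius(self) -> float:
        return float(np.max(np.abs(np.linalg.eigvals(self.companion_matrix()))))

    def validate_stationary(self) -> None:
        rho = self.spectral_radius()
        if rho >= 1.0:
            raise ValueError(
                f"non-stationary coupling: companion spectral radius {rho:.4f} >= 1; "
                "reduce coupling strength or self-coupling"
            )


@dataclass
class SyntheticDataset:
    """All epoched blocks of a simulated study, keyed by participant and condition."""

    blocks: dict[tuple[str, Condition], EpochedRoiSeries]
    truth: dict[Condition, GroundTruthNetwork]
    parcellation: Parcellation
    sampling_rate: float
    seed: int

    @property
    def participants(self) -> list[str]:
        return sorted({p for p, _ in self.blocks})

    @property
    def conditions(self) -> list[Condition]:
        return sorted({c for _, c in self.blocks})

    def block(self, participant: str, condition: Condition) -> EpochedRoiSeries:
        return self.blocks[(participant, condition)]

    def map_blocks(self, fn) -> "SyntheticDataset":
        """Return a copy with ``fn`` applied to every epoched block."""
        return SyntheticDataset(
            blocks={k: fn(v) for k, v in self.blocks.items()},
            truth=self.truth,
            parcellation=self.parcellation,
            sampling_rate=self.sampling_rate,
            seed=self.seed,
        )


@dataclass
class FsMatrixPair:
    """Forward and time-reversed shifted mutual-information matrices."""

    fs_forward: np.ndarray
    fs_reversal: np.ndarray
    T: int

    def __post_init__(self) -> None:
        self.fs_forward = np.asarray(self.fs_forward, dtype=float)
        self.fs_reversal = np.asarray(self.fs_reversal, dtype=float)
        if self.fs_forward.shape != self.fs_reversal.shape:
            raise ValueError(
                f"shape mismatch between forward {self.fs_forward.shape} and "
                f"reversal {self.fs_reversal.shape} matrices"
            )


@dataclass
class NonReversibility:
    """Scalar departure from temporal reversibility for one participant x condition."""

    nr: float
    condition: Condition | None = None
    participant_id: str | None = None


@dataclass
class NdteMatrix:
    """Per-trial normalized directed transfer entropy.

    ``f[target, source]`` is F_XY for source X -> target Y; inflow along
    rows, outflow along columns. The diagonal is undefined and stored as 0;
    pairs whose estimate failed are NaN (missing), never silently zero.
    """

    f: np.ndarray
    T: int
    trial: int | None = None

    def __post_init__(self) -> None:
        self.f = np.asarray(self.f, dtype=float)
        if self.f.ndim != 2 or self.f.shape[0] != self.f.shape[1]:
            raise ValueError("NDTE matrix must be square")


@dataclass
class ConditionConnectivity:
    """Group-level averaged NDTE matrix with its binary significance mask."""

    c_all: np.ndarray
    mask: np.ndarray
    condition: Condition | None = None

    def __post_init__(self) -> None:
        self.c_all = np.asarray(self.c_all, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.c_all.shape != self.mask.shape:
            raise ValueError("c_all and mask shapes differ")
        if np.any(self.c_all[~self.mask] != 0):
            raise ValueError("c_all must be zero wherever the mask is false")


@dataclass
class FlowVectors:
    """Per-ROI total inflow (row sums) and outflow (column sums) of C_All."""

    g_in: np.ndarray
    g_out: np.ndarray


@dataclass
class HubResult:
    """Trace of the iterative hub-set search for one flow direction.

    ``members`` holds the ROIs in the order they were added (sorted by the
    mode's flow, descending); ``g_hub``/``p`` record the combined flow score
    and Monte-Carlo p-value at each growth step. ``final_set`` is the longest
    significant prefix (possibly empty when even the top ROI is not
    distinguishable from the rest).
    """

    mode: str
    members: list[int]
    g_hub: list[float]
    p: list[float]
    final_set: list[int]
    alpha: float
    labels: list[str] = field(default_factory=list)

    @property
    def significant(self) -> bool:
        return len(self.final_set) > 0
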