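"""Synthetic trial-epoched ROI time series with known directed structure.

The generative family is a linear Gaussian vector autoregression (VAR):
every downstream estimator in the pipeline (shifted-correlation mutual
information, Gaussian transfer entropy) is covariance based, so a linear
Gaussian process makes closed-form oracles available for testing. Time
irreversibility is controlled through coupling asymmetry: a stationary
Gaussian VAR with a symmetric coupling matrix and equal noise variances
has a symmetric lagged cross-covariance and is therefore statistically
time-reversible, while directed (asymmetric) coupling breaks that symmetry.

Trials are independent realizations of the process, mirroring epoched EEG
where inter-trial intervals decorrelate successive epochs. All randomness
flows from a single seed through ``numpy.random.SeedSequence`` spawning, so
any participant/condition/trial subset is reproducible on its own.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .datatypes import (
    ATTENTION_LEVELS,
    CUE_LEVELS,
    Condition,
    EpochedRoiSeries,
    GroundTruthNetwork,
    Parcellation,
    SyntheticDataset,
)

__all__ = [
    "make_hub_network",
    "simulate_var",
    "simulate_reversibility_pair",
    "GroupConfig",
    "make_group_dataset",
]


def make_hub_network(
    n_rois: int,
    hub: int,
    mode: str,
    strength: float,
    order: int = 1,
    seed: int = 0,
    self_coupling: float = 0.3,
    background: float = 0.02,
    noise_sd: float = 1.0,
) -> GroundTruthNetwork:
    """Build a VAR network with one planted inflow or outflow hub.

    ``mode='in'``: the hub receives lag-1 coupling of magnitude ``strength``
    from every other ROI; ``mode='out'`` is the transposed pattern. All other
    cross-couplings are drawn small (uniform in ``[-background, background]``)
    and self-couplings are set to a stable AR(1) value. The network is
    rejected with a diagnostic if the companion-form spectral radius is >= 1.
    """
    if not 0 <= hub < n_rois:
        raise ValueError(f"hub index {hub} outside [0, {n_rois})")
    if mode not in ("in", "out"):
        raise ValueError(f"mode must be 'in' or 'out', got {mode!r}")
    rng = np.random.default_rng(seed)
    coupling = np.zeros((n_rois, n_rois, order))
    cross = rng.uniform(-background, background, size=(n_rois, n_rois))
    np.fill_diagonal(cross, 0.0)
    coupling[:, :, 0] = cross
    if mode == "in":
        coupling[hub, :, 0] = strength
        coupling[hub, hub, 0] = 0.0
    else:
        coupling[:, hub, 0] = strength
        coupling[hub, hub, 0] = 0.0
    coupling[:, :, 0][np.diag_indices(n_rois)] = self_coupling
    net = GroundTruthNetwork(coupling=coupling, noise_sd=np.full(n_rois, noise_sd))
    net.validate_stationary()
    return net


def simulate_var(
    net: GroundTruthNetwork,
    n_samples: int,
    n_trials: int,
    seed: int,
    burn_in: int | None = None,
    sampling_rate: float = 1000.0,
    t0: float = 0.0,
    parcellation: Parcellation | None = None,
    condition: Condition | None = None,
    participant_id: str | None = None,
) -> EpochedRoiSeries:
    """Simulate independent trial realizations of a stationary VAR process.

    Each trial starts from an independent noise history and runs through a
    burn-in of at least ten times the model order before samples are kept,
    so the retained segment is (approximately) a draw from the stationary
    distribution. All trials are advanced together, vectorized over the
    trial axis.
    """
    net.validate_stationary()
    n, p = net.n_rois, net.order
    if burn_in is None:
        burn_in = max(10 * p, 50)
    if burn_in < 10 * p:
        raise ValueError(f"burn_in must be >= 10 x order ({10 * p}), got {burn_in}")
    rng = np.random.default_rng(seed)
    total = burn_in + n_samples
    noise = rng.standard_normal((total, n_trials, n)) * net.noise_sd
    # hist[:, :, l] holds x_{t-l-1}
    hist = np.zeros((n_trials, n, p))
    out = np.empty((total, n_trials, n))
    coupling = net.coupling
    for t in range(total):
        x = np.einsum("ijl,kjl->ki", coupling, hist) + noise[t]
        out[t] = x
        if p > 1:
            hist[:, :, 1:] = hist[:, :, :-1]
        hist[:, :, 0] = x
    values = out[burn_in:].transpose(1, 2, 0)  # (trials, rois, time)
    parc = parcellation if parcellation is not None else Parcellation.generic(n)
    return EpochedRoiSeries(
        values=values,
        sampling_rate=sampling_rate,
        t0=t0,
        parcellation=parc,
        condition=condition,
        participant_id=participant_id,
    )


def _asymmetric_coupling(
    n_rois: int,
    asymmetry: float,
    rng: np.random.Generator,
    target_radius: float = 0.65,
) -> np.ndarray:
    """Coupling matrix interpolating between symmetric and directed.

    At ``asymmetry = 0`` the matrix is exactly symmetric (time-reversible
    dynamics); increasing ``asymmetry`` mixes in the antisymmetric part of a
    random matrix. The result is rescaled to a fixed spectral radius so that
    reversible and irreversible variants have comparable dynamic range.
    """
    if not 0.0 <= asymmetry <= 1.0:
        raise ValueError(f"asymmetry must lie in [0, 1], got {asymmetry}")
    base = rng.standard_normal((n_rois, n_rois))
    sym = 0.5 * (base + base.T)
    anti = 0.5 * (base - base.T)
    raw = sym + asymmetry * anti
    radius = np.max(np.abs(np.linalg.eigvals(raw)))
    return raw * (target_radius / radius)


def simulate_reversibility_pair(
    n_rois: int,
    asymmetry: float,
    n_samples: int,
    seed: int,
    n_trials: int = 1,
    sampling_rate: float = 1000.0,
) -> tuple[EpochedRoiSeries, EpochedRoiSeries]:
    """Matched pair of simulations differing only in coupling asymmetry.

    The first element uses a symmetric coupling matrix (time-reversible
    process); the second mixes in directed coupling with weight
    ``asymmetry``. Both share the same random base matrix and the same
    innovation stream, so the contrast isolates irreversibility.
    """
    root = np.random.SeedSequence(seed)
    coup_seed, noise_seed = root.spawn(2)
    # fresh generators from the same seed draw the same base matrix
    coup_sym = _asymmetric_coupling(n_rois, 0.0, np.random.default_rng(coup_seed))
    coup_asym = _asymmetric_coupling(n_rois, asymmetry, np.random.default_rng(coup_seed))
    noise_int = int(noise_seed.generate_state(1)[0] % (2**31))
    pair = []
    for coup in (coup_sym, coup_asym):
        net = GroundTruthNetwork(coupling=coup[:, :, None], noise_sd=np.ones(n_rois))
        pair.append(
            simulate_var(
                net,
                n_samples=n_samples,
                n_trials=n_trials,
                seed=noise_int,
                sampling_rate=sampling_rate,
            )
        )
    return pair[0], pair[1]


@dataclass
class GroupConfig:
    """Study-level configuration for the group generator.

    Defaults emulate the recorded study: 28 participants, a 2 (attention) x
    2 (cue) x 2 (motion) within-subject design, 68 cortical ROIs sampled at
    1 kHz with 300-sample epochs (the 0-300 ms analysis window), and roughly
    balanced trial counts per cell. ``condition_asymmetry`` plants extra
    coupling asymmetry — hence extra temporal irreversibility — in chosen
    cells; the default boosts the looming x intensity cells, the effect the
    factorial analysis is designed to detect.
    """

    n_participants: int = 28
    n_trials: int = 40
    n_rois: int = 68
    n_samples: int = 300
    sampling_rate: float = 1000.0
    epoch_t0: float = 0.0
    order: int = 1
    base_asymmetry: float = 0.15
    condition_asymmetry: dict[tuple[str, str, str], float] = field(
        default_factory=lambda: {
            ("*", "intensity", "looming"): 0.45,
        }
    )
    participant_jitter_sd: float = 0.05
    motion_levels: tuple[str, ...] = ("looming", "receding")
    seed: int = 0

    def conditions(self) -> list[Condition]:
        conds = [
            Condition(a, c, m).validate()
            for a, c, m in itertools.product(ATTENTION_LEVELS, CUE_LEVELS, self.motion_levels)
        ]
        return conds

    def asymmetry_for(self, cond: Condition) -> float:
        alpha = self.base_asymmetry
        for key, boost in self.condition_asymmetry.items():
            if len(key) != 3:
                raise ValueError(f"condition_asymmetry key must be a factor triple, got {key!r}")
            att, cue, mot = key
            for name, val, levels in (
                ("attention", att, ATTENTION_LEVELS),
                ("cue", cue, CUE_LEVELS),
                ("motion", mot, ("looming", "receding", "static")),
            ):
                if val != "*" and val not in levels:
                    raise ValueError(f"invalid {name} level {val!r} in condition_asymmetry")
            if (
                (att == "*" or att == cond.attention)
                and (cue == "*" or cue == cond.cue)
                and (mot == "*" or mot == cond.motion)
            ):
                alpha += boost
        return min(alpha, 1.0)


def make_group_dataset(config: GroupConfig) -> SyntheticDataset:
    """Simulate a full multi-participant factorial study.

    Every condition has a group-level ground-truth network whose coupling
    asymmetry is set by the config; each participant gets a jittered copy
    (couplings multiplied by ``1 + N(0, participant_jitter_sd)`` elementwise)
    so that between-participant variability is present, as in real data.
    """
    conditions = config.conditions()
    root = np.random.SeedSequence(config.seed)
    net_seed, part_root = root.spawn(2)

    truth: dict[Condition, GroundTruthNetwork] = {}
    group_coupling: dict[Condition, np.ndarray] = {}
    for cond in conditions:
        # fresh generator per condition: same base matrix, condition-specific asymmetry
        rng = np.random.default_rng(net_seed)
        coup = _asymmetric_coupling(config.n_rois, config.asymmetry_for(cond), rng)
        group_coupling[cond] = coup
        truth[cond] = GroundTruthNetwork(
            coupling=coup[:, :, None], noise_sd=np.ones(config.n_rois)
        )

    parc = (
        Parcellation.desikan_killiany()
        if config.n_rois == 68
        else Parcellation.generic(config.n_rois)
    )
    blocks: dict[tuple[str, Condition], EpochedRoiSeries] = {}
    part_seeds = part_root.spawn(config.n_participants)
    for p_idx, p_seed in enumerate(part_seeds):
        pid = f"sub{p_idx + 1:02d}"
        jitter_seed, *cond_seeds = p_seed.spawn(1 + len(conditions))
        jitter = 1.0 + config.participant_jitter_sd * np.random.default_rng(
            jitter_seed
        ).standard_normal((config.n_rois, config.n_rois))
        for cond, c_seed in zip(conditions, cond_seeds):
            coup = group_coupling[cond] * jitter
            # guard stationarity after jitter by shrinking if needed
            radius = np.max(np.abs(np.linalg.eigvals(coup)))
            if radius >= 0.95:
                coup = coup * (0.9 / radius)
            net = GroundTruthNetwork(coupling=coup[:, :, None], noise_sd=np.ones(config.n_rois))
            trial_seed = int(c_seed.generate_state(1)[0] % (2**31))
            blocks[(pid, cond)] = simulate_var(
                net,
                n_samples=config.n_samples,
                n_trials=config.n_trials,
                seed=trial_seed,
                sampling_rate=config.sampling_rate,
                t0=config.epoch_t0,
                parcellation=parc,
                condition=cond,
                participant_id=pid,
            )
    return SyntheticDataset(
        blocks=blocks,
        truth=truth,
        parcellation=parc,
        sampling_rate=config.sampling_rate,
        seed=config.seed,
    )
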