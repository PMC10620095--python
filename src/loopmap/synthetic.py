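"""Seeded synthetic data emulating the cortico-cerebellar mapping study.

Four generators produce the data structures the analysis stages consume:

* :func:`gen_anatomy` — mossy-fiber-terminal and Purkinje-soma point clouds
  with per-lobule Poisson intensities and per-mouse infection-rate scaling;
* :func:`gen_ephys` — trial-aligned spike trains with trial-type-selective
  delay-epoch ramps, plus Purkinje units carrying a complex-spike (CS) stream
  with an enforced simple-spike (SS) pause after each CS;
* :func:`gen_behavior` — photostimulation sessions over a 4 × 4 spot grid with
  configurable per-condition performance bias;
* :func:`gen_embeddings` — smooth 32-dimensional per-frame video embeddings
  and movement-coupled spike counts for the movement-GLM control.

All randomness flows from one root seed through named sub-streams
(:func:`stream`), so each stage can be regenerated independently and
identically.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from . import task
from .atlas import AtlasSpec, default_atlas
from .purkinje import psth_time_base
from .selectivity import UnitRecording

log = logging.getLogger(__name__)

EMBEDDING_DIM = 32  # dimensionality of the video embedding space
FRAME_STEPS_S = (0.025, 0.017)  # the two camera frame steps

PHOTOSTIM_SPOTS = tuple(f"s{i:02d}" for i in range(1, 17))  # 4 × 4 grid
PHOTOSTIM_EPOCHS = ("sample", "delay", "response")


class ConfigurationError(ValueError):
    """Raised when a generation config is internally inconsistent."""


def stream(seed: int, *keys: str) -> np.random.Generator:
    """Named random sub-stream derived from the root seed.

    Each key is hashed (CRC-32) into the entropy of a ``SeedSequence`` so
    that e.g. ``stream(seed, "anatomy")`` and ``stream(seed, "ephys")`` are
    independent but individually reproducible.
    """
    entropy = [int(seed)] + [zlib.crc32(k.encode()) for k in keys]
    return np.random.default_rng(np.random.SeedSequence(entropy))


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------

def _default_input_intensity() -> dict[str, float]:
    # expected mossy-fiber terminals per mm³: ALM input reaches the
    # conjunction and input-dominant territories, none elsewhere
    regions = [
        "med-SIM", "med-Crus 1", "med-Crus 2", "Lob VII",      # conjunction
        "lat-SIM", "lat-Crus 1", "lat-Crus 2", "PRM",          # input-dominant
    ]
    return {r: 150.0 for r in regions}


def _default_output_intensity() -> dict[str, float]:
    # expected fastigial-projecting Purkinje somata per mm³
    regions = [
        "med-SIM", "med-Crus 1", "med-Crus 2", "Lob VII",      # conjunction
        "COPY", "Lob II", "Lob III", "Lob IV", "Lob V",
        "Lob VI", "Lob VIII", "Lob IX", "Lob X",               # output-dominant
    ]
    return {r: 120.0 for r in regions}


@dataclass
class GenerationConfig:
    """Parameters of the synthetic study; defaults mirror the study design."""

    seed: int = 0

    # --- anatomy ---
    input_intensity_per_mm3: dict[str, float] = field(
        default_factory=_default_input_intensity)
    output_intensity_per_mm3: dict[str, float] = field(
        default_factory=_default_output_intensity)
    mouse_rate_sigma: float = 0.4  # lognormal sd of infection-rate multiplier
    pathway: str = "fastigial"
    collapse_posterior_tip: bool = False

    # --- electrophysiology ---
    baseline_rate_hz: float = 40.0
    selectivity_amplitude_hz: float = 5.0  # delay-epoch mean rate difference
    selectivity_shape: str = "ramp"  # "ramp" (0→2A across delay) or "step" (+A)
    frac_selective: float = 1.0
    response_gain_hz: float = 5.0  # untuned motor drive during response epoch
    cs_rate_hz: float = 1.0
    pause_ms: float = 10.0  # enforced SS silence after each CS
    trials_per_type: int = 30
    error_rate: float = 0.15
    frac_purkinje: float = 0.2

    # --- behavior ---
    control_performance: dict[str, float] = field(
        default_factory=lambda: {t: 0.785 for t in task.TRIAL_TYPES})
    #: behavioral variability across the hierarchy (s.d. of the per-mouse and
    #: per-session offsets to P(correct)) — the "normal behavioral
    #: variability" the bootstrap's null hypothesis refers to
    mouse_perf_sigma: float = 0.05
    session_perf_sigma: float = 0.05
    early_lick_rate: float = 0.05
    ignore_rate: float = 0.02
    stim_fraction: float = 0.5
    #: (spot, epoch) → additive change in P(correct) on stimulated trials
    stim_bias: dict[tuple[str, str], float] = field(default_factory=dict)
    #: conditions stimulation trials are drawn from; None = the full
    #: 16-spot × 3-epoch grid.  Single-condition sessions mirror the
    #: dedicated one-spot experiments.
    active_conditions: list[tuple[str, str]] | None = None

    # --- embeddings ---
    embedding_dim: int = EMBEDDING_DIM
    frame_step_s: float = 0.025
    embedding_smooth_s: float = 0.05  # temporal correlation scale of the latent
    coupling_scale: float = 0.3  # log-rate weight magnitude of coupled dims
    coupling_density: float = 0.25  # fraction of embedding dims with coupling
    coupling_lag_steps: int = 0
    embedding_type_shift: float = 0.0  # trial-type shift of the latent (delay on)

    def __post_init__(self):
        if self.embedding_dim != EMBEDDING_DIM:
            raise ConfigurationError(
                f"embedding dimension is fixed at {EMBEDDING_DIM}")
        if self.frame_step_s not in FRAME_STEPS_S:
            raise ConfigurationError(
                f"frame step must be one of {FRAME_STEPS_S} s")
        if self.trials_per_type < 1:
            raise ConfigurationError("trials_per_type must be >= 1")
        for name in ("baseline_rate_hz", "cs_rate_hz", "response_gain_hz"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        for t, p in self.control_performance.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"performance for {t!r} outside [0, 1]")
        for (spot, epoch), delta in self.stim_bias.items():
            for t, p in self.control_performance.items():
                if not 0.0 <= p + delta <= 1.0:
                    raise ConfigurationError(
                        f"stim performance for {spot}/{epoch} outside [0, 1]")

    # YAML round-trip -------------------------------------------------

    def to_yaml(self, path) -> None:
        d = self.__dict__.copy()
        d["stim_bias"] = {f"{s}|{e}": v for (s, e), v in d["stim_bias"].items()}
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "GenerationConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        bias = {}
        for key, v in (d.get("stim_bias") or {}).items():
            s, e = key.split("|")
            bias[(s, e)] = v
        d["stim_bias"] = bias
        if d.get("active_conditions") is not None:
            d["active_conditions"] = [tuple(c) for c in d["active_conditions"]]
        return cls(**d)

    def with_(self, **kw) -> "GenerationConfig":
        return replace(self, **kw)


# --------------------------------------------------------------------------
# anatomy
# --------------------------------------------------------------------------

POINT_COLUMNS = ["x_um", "y_um", "z_um", "hemisphere", "lobule", "mouse_id", "marker"]


def gen_anatomy(
    config: GenerationConfig,
    atlas: AtlasSpec | None = None,
    n_mice: int = 5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate (inputs, outputs) anatomical point clouds.

    Inputs are mossy-fiber terminals in both hemispheres; outputs are
    retrogradely labelled Purkinje somata, which the tracing restricts to a
    single (right) hemisphere.  Per-region counts are Poisson with mean
    ``intensity × region volume × per-mouse multiplier``; the multiplier is
    lognormal and models infection-rate variability between injection cases.
    Points are labelled with the base lobule; the medial/lateral split is a
    downstream operation.
    """
    if n_mice < 1:
        raise ConfigurationError("n_mice must be >= 1")
    atlas = atlas or default_atlas()
    valid = set(atlas.region_labels(config.pathway)) | set(atlas.names)
    for intensity in (config.input_intensity_per_mm3, config.output_intensity_per_mm3):
        for label, rate in intensity.items():
            if label not in valid:
                raise ConfigurationError(f"unknown lobule {label!r} in config")
            if rate < 0:
                raise ConfigurationError(f"negative intensity for {label!r}")

    rng = stream(config.seed, "anatomy")
    mults = rng.lognormal(mean=0.0, sigma=config.mouse_rate_sigma, size=n_mice)

    def _cloud(intensity: dict[str, float], hemis: tuple[str, ...], marker: str):
        rows = []
        for m in range(n_mice):
            for label in sorted(intensity):
                lam_region = (
                    intensity[label]
                    * atlas.volume_voxels(label, config.pathway) / 1e6
                    * mults[m]
                )
                for hemi in hemis:
                    # volume_voxels spans both hemispheres; each hemisphere
                    # holds half the expected count
                    n = rng.poisson(lam_region / 2.0)
                    if n == 0:
                        continue
                    (xlo, xhi), (ylo, yhi), (zlo, zhi) = atlas.sample_box(
                        label, config.pathway)
                    x = rng.uniform(xlo, xhi, n)
                    if hemi == "L":
                        x = -x
                    y = rng.uniform(ylo, yhi, n)
                    z = rng.uniform(zlo, zhi, n)
                    if config.collapse_posterior_tip:
                        y = np.minimum(y, atlas.posterior_cap_um)
                    base = atlas.lobule(label).name
                    rows.append(pd.DataFrame({
                        "x_um": x, "y_um": y, "z_um": z,
                        "hemisphere": hemi, "lobule": base,
                        "mouse_id": m, "marker": marker,
                    }))
        if not rows:
            return pd.DataFrame(columns=POINT_COLUMNS)
        return pd.concat(rows, ignore_index=True)

    inputs = _cloud(config.input_intensity_per_mm3, ("L", "R"), "mossy-fiber terminal")
    outputs = _cloud(config.output_intensity_per_mm3, ("R",), "Purkinje soma")
    return inputs, outputs


# --------------------------------------------------------------------------
# electrophysiology
# --------------------------------------------------------------------------

_SUBBIN_S = 0.05  # resolution of the piecewise-constant rate profiles


def _rate_profile(config: GenerationConfig, preferred: str | None):
    """Per-trial-type rate vectors on the sub-bin grid (go-cue aligned)."""
    edges = np.arange(task.TRIAL_START_S, task.TRIAL_END_S + 1e-9, _SUBBIN_S)
    t = 0.5 * (edges[:-1] + edges[1:])
    rates = {}
    d0, d1 = task.EPOCHS["delay"]
    r0, r1 = task.EPOCHS["response"]
    for ttype in task.TRIAL_TYPES:
        r = np.full(t.size, config.baseline_rate_hz)
        r[(t >= r0) & (t < r1)] += config.response_gain_hz
        if preferred is not None and ttype == preferred:
            in_delay = (t >= d0) & (t < d1)
            amp = config.selectivity_amplitude_hz
            if config.selectivity_shape == "step":
                r[in_delay] += amp
            else:  # linear ramp from 0 to 2A: delay-epoch mean difference = A
                frac = (t[in_delay] - d0) / (d1 - d0)
                r[in_delay] += 2.0 * amp * frac
        if np.any(r < 0):
            log.warning("rate clipped at 0 for trial type %s", ttype)
            r = np.clip(r, 0.0, None)
        rates[ttype] = r
    return edges, rates


def _poisson_spikes(rng, edges, rate):
    counts = rng.poisson(rate * np.diff(edges))
    times = np.concatenate([
        rng.uniform(edges[i], edges[i + 1], c)
        for i, c in enumerate(counts) if c
    ]) if counts.sum() else np.empty(0)
    return np.sort(times)


def gen_trial_table(config: GenerationConfig, rng) -> pd.DataFrame:
    n = config.trials_per_type
    types = np.repeat(task.TRIAL_TYPES, n)
    rng.shuffle(types)
    outcome = np.where(rng.random(types.size) < config.error_rate,
                       "error", "correct")
    return pd.DataFrame({
        "trial_id": np.arange(types.size),
        "trial_type": types,
        "outcome": outcome,
        "photostim": "none",
    })


def gen_ephys(
    config: GenerationConfig,
    n_units: int,
    region_labels: list[str] | None = None,
) -> tuple[list[UnitRecording], pd.DataFrame]:
    """Generate one session: a shared trial table and ``n_units`` recordings.

    Spike trains are inhomogeneous Poisson on a 50-ms piecewise-constant rate
    grid.  Selective units add a delay-epoch ramp (or step) of configured
    amplitude on their preferred trial type.  A configured fraction of units
    are Purkinje cells: they carry a CS stream and SS are deleted inside the
    configured pause window after each CS.
    """
    region_labels = region_labels or ["med-Crus 1"]
    rng = stream(config.seed, "ephys")
    trials = gen_trial_table(config, rng)
    units: list[UnitRecording] = []
    for u in range(n_units):
        selective = rng.random() < config.frac_selective
        preferred = rng.choice(task.TRIAL_TYPES) if selective else None
        edges, rates = _rate_profile(config, preferred)
        is_pkj = rng.random() < config.frac_purkinje
        spikes, cs = {}, ({} if is_pkj else None)
        for tid, ttype in zip(trials.trial_id, trials.trial_type):
            ss = _poisson_spikes(rng, edges, rates[ttype])
            if is_pkj:
                cst = _poisson_spikes(
                    rng, edges, np.full(edges.size - 1, config.cs_rate_hz))
                ss = enforce_cs_pause(ss, cst, config.pause_ms)
                cs[tid] = cst
            spikes[tid] = ss
        region = region_labels[u % len(region_labels)]
        units.append(UnitRecording(
            unit_id=u, spikes=spikes, cs_spikes=cs,
            coords_um=(2000.0, 3000.0, 1000.0), region=region,
            unit_class="purkinje" if is_pkj else "ss-only",
            meta={"preferred": preferred,
                  "amplitude_hz": config.selectivity_amplitude_hz if selective else 0.0},
        ))
    return units, trials


def enforce_cs_pause(ss: np.ndarray, cs: np.ndarray, pause_ms: float) -> np.ndarray:
    """Delete SS falling within ``pause_ms`` after any CS."""
    if ss.size == 0 or cs.size == 0:
        return ss
    keep = np.ones(ss.size, bool)
    w = pause_ms / 1000.0
    for c in cs:
        keep &= ~((ss >= c) & (ss < c + w))
    return ss[keep]


# --------------------------------------------------------------------------
# CS response-type archetypes
# --------------------------------------------------------------------------


def _bump(t, center, width, amp):
    return amp * np.exp(-0.5 * ((t - center) / width) ** 2)


def cs_response_templates() -> tuple[list[str], np.ndarray]:
    """The six CS response-type archetypes as z-scored 102-bin templates.

    The bank covers the qualitative CS modulations seen in the task:
    transients at epoch transitions, a trial-start transient preceding the
    sample epoch (pole-motor sound), a buildup of activity before the motor
    response, sustained up/down modulation during the response, and a
    sustained task-long modulation.
    """
    t = psth_time_base()
    s0 = task.SAMPLE_START_S
    d0, go = task.DELAY_START_S, task.GO_CUE_S
    r1 = task.TRIAL_END_S
    templates = {
        "epoch-transition transient": (
            _bump(t, s0, 0.10, 2.0) + _bump(t, d0, 0.10, 2.0)
            + _bump(t, go, 0.10, 2.0)),
        "trial-start transient": _bump(t, s0 - 0.3, 0.12, 2.5),
        "pre-response buildup": np.where(
            (t >= d0) & (t < go), 2.0 * (t - d0) / (go - d0),
            np.where(t >= go, 2.0 * np.exp(-(t - go) / 0.4), 0.0)),
        "response modulation up": np.where(
            t >= go, 2.0 * np.minimum((t - go) / 0.3, 1.0), 0.0),
        "response modulation down": np.where(
            t >= go, -1.8 * np.minimum((t - go) / 0.3, 1.0), 0.0),
        "sustained task modulation": np.where(
            (t >= s0) & (t < r1), 1.5 * np.minimum((t - s0) / 0.5, 1.0), 0.0),
    }
    names = list(templates)
    return names, np.vstack([templates[n] for n in names])


def gen_cs_psth_archetypes(
    n_per_type: int = 40,
    noise_sigma_frac: float = 0.3,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Synthetic z-scored CS PSTHs: one archetype per response type.

    Each unit is its type's template plus i.i.d. Gaussian noise with
    sigma = ``noise_sigma_frac`` × the template's peak absolute amplitude.

    Returns (psths ``(n_units, 102)``, true labels, type names).
    """
    names, templates = cs_response_templates()
    rng = stream(seed, "cs-archetypes")
    psths, labels = [], []
    for k, tpl in enumerate(templates):
        sigma = noise_sigma_frac * np.abs(tpl).max()
        psths.append(tpl + rng.normal(0.0, sigma, (n_per_type, tpl.size)))
        labels.append(np.full(n_per_type, k))
    return np.vstack(psths), np.concatenate(labels), names


# --------------------------------------------------------------------------
# behavior
# --------------------------------------------------------------------------

BEHAVIOR_COLUMNS = ["mouse_id", "session_id", "trial_id", "trial_type",
                    "stim_spot", "stim_epoch", "outcome"]


def gen_behavior(
    config: GenerationConfig,
    n_mice: int,
    sessions_per_mouse: int,
    trials_per_session: int,
) -> pd.DataFrame:
    """Generate a photostimulation behavior dataset (one row per trial).

    Each trial draws a type, a condition (control, or one of 16 spots × 3
    epochs with probability ``stim_fraction``) and an outcome: early-lick and
    ignore trials occur at their configured rates; among the remaining
    (scoreable) trials the choice is Bernoulli with the control performance
    plus any configured per-(spot, epoch) bias.
    """
    if min(n_mice, sessions_per_mouse, trials_per_session) < 1:
        raise ConfigurationError("counts must be >= 1")
    rng = stream(config.seed, "behavior")
    if config.active_conditions is None:
        conditions = [(s, e) for e in PHOTOSTIM_EPOCHS
                      for s in PHOTOSTIM_SPOTS]
    else:
        conditions = list(config.active_conditions)
    spot_of = np.array([c[0] for c in conditions])
    epoch_of = np.array([c[1] for c in conditions])
    rows = []
    for m in range(n_mice):
        mouse_off = rng.normal(0.0, config.mouse_perf_sigma)
        for s in range(sessions_per_mouse):
            sess_off = mouse_off + rng.normal(0.0, config.session_perf_sigma)
            ttype = rng.choice(task.TRIAL_TYPES, trials_per_session)
            stim = rng.random(trials_per_session) < config.stim_fraction
            cond = rng.integers(0, len(conditions), trials_per_session)
            spot = np.where(stim, spot_of[cond], "none")
            epoch = np.where(stim, epoch_of[cond], "none")
            u = rng.random(trials_per_session)
            outcome = np.empty(trials_per_session, dtype=object)
            early = u < config.early_lick_rate
            ignore = (~early) & (u < config.early_lick_rate + config.ignore_rate)
            outcome[early] = "early-lick"
            outcome[ignore] = "ignore"
            scoreable = ~(early | ignore)
            p = np.array([config.control_performance[t] for t in ttype])
            p = p + sess_off
            for i in np.flatnonzero(stim):
                p[i] += config.stim_bias.get((spot[i], epoch[i]), 0.0)
            correct = rng.random(trials_per_session) < np.clip(p, 0.0, 1.0)
            outcome[scoreable & correct] = "correct"
            outcome[scoreable & ~correct] = "error"
            rows.append(pd.DataFrame({
                "mouse_id": m, "session_id": f"m{m}_s{s}",
                "trial_id": np.arange(trials_per_session),
                "trial_type": ttype, "stim_spot": spot, "stim_epoch": epoch,
                "outcome": outcome,
            }))
    return pd.concat(rows, ignore_index=True)


# --------------------------------------------------------------------------
# video embeddings
# --------------------------------------------------------------------------

@dataclass
class EmbeddingSession:
    """Per-frame embeddings with movement-coupled spike counts.

    ``embeddings`` is ``(n_frames, 32)`` over all trials concatenated;
    ``counts`` is ``(n_units, n_frames)``; ``trial_index`` maps each frame to
    its trial.  ``true_weights``/``true_lag`` record the generating model for
    recovery tests.
    """
    step_s: float
    frame_t: np.ndarray          # go-cue-aligned time of each frame
    trial_index: np.ndarray      # (n_frames,) int trial of each frame
    trial_type: np.ndarray       # (n_trials,) labels
    embeddings: np.ndarray       # (n_frames, 32)
    counts: np.ndarray           # (n_units, n_frames)
    true_weights: np.ndarray     # (n_units, 32)
    true_lag: int


def gen_embeddings(
    config: GenerationConfig,
    n_trials: int = 40,
    n_units: int = 1,
    direct_selectivity_hz: float = 0.0,
    base_rate_hz: float = 40.0,
) -> EmbeddingSession:
    """Generate smooth latent embeddings and spike counts driven by them.

    The latent is temporally smoothed Gaussian noise (unit variance,
    correlation scale ``embedding_smooth_s``).  With
    ``embedding_type_shift > 0`` the first four dimensions acquire a
    trial-type-dependent offset from delay onset onward, creating
    movement-explained selectivity.  Each unit's log rate is linear in the
    embedding at ``coupling_lag_steps`` frames in the past; a nonzero
    ``direct_selectivity_hz`` adds delay-epoch selectivity that movement does
    not explain.
    """
    rng = stream(config.seed, "embeddings")
    step = config.frame_step_s
    n_frames = int(round((task.TRIAL_END_S - task.TRIAL_START_S) / step))
    t_trial = task.TRIAL_START_S + (np.arange(n_frames) + 0.5) * step

    sigma_frames = max(config.embedding_smooth_s / step, 1e-6)
    kernel_half = int(np.ceil(4 * sigma_frames))
    kk = np.arange(-kernel_half, kernel_half + 1)
    kernel = np.exp(-0.5 * (kk / sigma_frames) ** 2)
    kernel /= np.sqrt(np.sum(kernel ** 2))  # preserve unit variance

    # balanced, shuffled trial types (as in the task's random interleaving)
    types = np.array(task.TRIAL_TYPES * (n_trials // 2 + 1))[:n_trials]
    rng.shuffle(types)
    emb = np.empty((n_trials * n_frames, EMBEDDING_DIM))
    for tr in range(n_trials):
        white = rng.normal(size=(n_frames + 2 * kernel_half, EMBEDDING_DIM))
        smooth = np.vstack([
            np.convolve(white[:, d], kernel, mode="valid")
            for d in range(EMBEDDING_DIM)]).T
        if config.embedding_type_shift:
            sign = 1.0 if types[tr] == "lick-right" else -1.0
            on = t_trial >= task.DELAY_START_S
            smooth[on, :4] += sign * config.embedding_type_shift
        emb[tr * n_frames:(tr + 1) * n_frames] = smooth

    n_coupled = max(1, int(round(config.coupling_density * EMBEDDING_DIM)))
    weights = np.zeros((n_units, EMBEDDING_DIM))
    for u in range(n_units):
        if config.embedding_type_shift:
            # guarantee the unit reads the type-shifted dimensions so that
            # its selectivity really is movement-borne
            extra = rng.choice(np.arange(4, EMBEDDING_DIM),
                               max(n_coupled - 4, 0), replace=False)
            dims = np.concatenate([np.arange(4), extra]).astype(int)
        else:
            dims = rng.choice(EMBEDDING_DIM, n_coupled, replace=False)
        weights[u, dims] = rng.choice([-1.0, 1.0], dims.size) * config.coupling_scale

    lag = int(config.coupling_lag_steps)
    trial_index = np.repeat(np.arange(n_trials), n_frames)
    frame_t = np.tile(t_trial, n_trials)
    in_delay = (frame_t >= task.DELAY_START_S) & (frame_t < task.GO_CUE_S)
    counts = np.empty((n_units, emb.shape[0]), dtype=np.int64)
    for u in range(n_units):
        drive = np.zeros(emb.shape[0])
        for tr in range(n_trials):
            sl = slice(tr * n_frames, (tr + 1) * n_frames)
            e = emb[sl]
            # rate at frame i follows the embedding at frame i - lag
            shifted = np.empty_like(e)
            if lag >= 0:
                shifted[lag:] = e[:n_frames - lag] if lag else e
                shifted[:lag] = e[0]
            else:
                shifted[:lag] = e[-lag:]
                shifted[lag:] = e[-1]
            drive[sl] = shifted @ weights[u]
        rate = base_rate_hz * np.exp(drive - 0.5 * np.sum(weights[u] ** 2))
        if direct_selectivity_hz:
            pref = np.isin(trial_index, np.flatnonzero(types == "lick-right"))
            rate = rate + direct_selectivity_hz * (pref & in_delay)
        counts[u] = rng.poisson(np.clip(rate, 0.0, None) * step)

    return EmbeddingSession(
        step_s=step, frame_t=frame_t, trial_index=trial_index,
        trial_type=types, embeddings=emb, counts=counts,
        true_weights=weights, true_lag=lag)
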