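"""Synthetic two-group, two-condition EEG cohorts with known ground truth.

The generator emulates the statistical structure the network analysis
assumes, so that every downstream stage (filtering, wPLI, SWP, hub
detection, permutation inference, efficiency regression) can be verified
against a known answer:

* Each group owns a ground-truth weighted network per frequency band — a
  Watts–Strogatz-style ring lattice rewired with probability ``p`` — so
  the groups differ in planted topology (clustering), the quantity the
  analysis is meant to recover.  The default rewiring probabilities
  (control 0.1, dyslexic 0.5) plant a clustering deficit in the dyslexic
  group's networks.
* Channels are narrowband stochastic oscillators (sinusoids with
  Ornstein–Uhlenbeck phase drift).  Every true edge contributes a shared
  latent oscillation to both of its endpoint channels with a fixed,
  nonzero phase lag (drawn from ±[π/8, 3π/8], never 0 or π, so the
  lag-sensitive wPLI can see every edge) plus wrapped-Gaussian phase
  jitter whose spread shrinks with coupling strength.  Uncoupled channels
  share nothing but sensor noise, so their wPLI stays at the estimator's
  noise floor.
* A configurable fraction of trials receives injected high-amplitude
  transients (±400 µV) so the ±200 µV artifact rejection rule has work to
  do; clean signals stay within roughly ±50 µV.
* Behaviour: per-subject inverse efficiency is generated as a linear
  function of that subject's small-world propensity ϕ (negative slope by
  default), with lognormal trial RTs and Bernoulli accuracy from a
  logistic link — giving the efficiency regression a planted slope to
  recover.

Sample sizes and epoch counts default to the study conditions: 20
control and 24 dyslexic readers, 32 ± 5 clean epochs per subject and
condition for controls, 21 ± 7 for the dyslexic group, 800 ms epochs at
250 Hz.  All randomness flows from a single integer seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

from .montage import Montage, standard_montage, CHANNELS_40
from .preprocess import BandDefinition, CANONICAL_BANDS, EpochSet

__all__ = [
    "GroundTruthNetwork", "BehavioralRecord", "CohortTruth",
    "make_ground_truth_network", "simulate_band_epochs",
    "simulate_cohort_epochs", "simulate_behavior",
    "default_cohort_truth", "cohort_truth_from_yaml",
]


@dataclass
class GroundTruthNetwork:
    """A planted weighted coupling network with per-edge phase lags.

    ``adjacency`` is symmetric, nonnegative, zero-diagonal (coupling
    strengths); ``lag`` is antisymmetric (``lag[i, j] = −lag[j, i]``, the
    phase by which channel i leads channel j on that edge, radians).
    """

    n_nodes: int
    adjacency: np.ndarray
    lag: np.ndarray
    topology_params: dict = field(default_factory=dict)

    def __post_init__(self):
        a = np.asarray(self.adjacency, dtype=float)
        l = np.asarray(self.lag, dtype=float)
        if a.shape != (self.n_nodes, self.n_nodes):
            raise ValueError("adjacency shape mismatch")
        if not np.allclose(a, a.T) or (a < 0).any() or np.diag(a).any():
            raise ValueError("adjacency must be symmetric, nonnegative, "
                             "zero-diagonal")
        if not np.allclose(l, -l.T):
            raise ValueError("lag must be antisymmetric")
        self.adjacency, self.lag = a, l

    def edges(self):
        """Yield (i, j, weight, lag_ij) for every i < j with weight > 0."""
        iu = np.triu_indices(self.n_nodes, k=1)
        for i, j in zip(*iu):
            if self.adjacency[i, j] > 0:
                yield int(i), int(j), self.adjacency[i, j], self.lag[i, j]


@dataclass(frozen=True)
class BehavioralRecord:
    """One trial's behavioural outcome."""

    subject_id: str
    group: str
    condition: str
    rt_ms: float
    correct: bool

    def __post_init__(self):
        if self.rt_ms <= 0:
            raise ValueError("rt_ms must be positive")


def make_ground_truth_network(
    n_nodes: int,
    neighbors_k: int,
    rewiring_p: float,
    weight_scale: float = 1.0,
    seed: int | None = None,
) -> GroundTruthNetwork:
    """Watts–Strogatz-style substrate with random weights and lags.

    A ring lattice where every node connects to its ``neighbors_k``
    nearest neighbours is rewired edge-by-edge with probability
    ``rewiring_p``; weights are uniform(0.5, 1) · ``weight_scale``; each
    edge gets a phase lag of random sign drawn uniformly from
    [π/8, 3π/8] in magnitude.
    """
    if not (n_nodes > neighbors_k >= 2) or neighbors_k % 2:
        raise ValueError("need n_nodes > neighbors_k ≥ 2 with even k")
    if not 0 <= rewiring_p <= 1:
        raise ValueError("rewiring_p must lie in [0, 1]")
    if weight_scale <= 0:
        raise ValueError("weight_scale must be positive")
    import networkx as nx

    rng = np.random.default_rng(seed)
    g = nx.watts_strogatz_graph(
        n_nodes, neighbors_k, rewiring_p,
        seed=int(rng.integers(0, 2 ** 31 - 1)))
    adj = np.zeros((n_nodes, n_nodes))
    lag = np.zeros((n_nodes, n_nodes))
    for i, j in g.edges():
        w = rng.uniform(0.5, 1.0) * weight_scale
        lam = rng.choice([-1.0, 1.0]) * rng.uniform(np.pi / 8, 3 * np.pi / 8)
        adj[i, j] = adj[j, i] = w
        lag[i, j], lag[j, i] = lam, -lam
    return GroundTruthNetwork(
        n_nodes=n_nodes, adjacency=adj, lag=lag,
        topology_params={"neighbors_k": neighbors_k,
                         "rewiring_p": rewiring_p,
                         "weight_scale": weight_scale})


def make_paired_ground_truth_networks(
    n_nodes: int,
    neighbors_k: int,
    rewiring_p_by_group: dict,
    weight_scale: float = 1.0,
    seed: int | None = None,
) -> dict:
    """One Watts–Strogatz-style network per group, from common random draws.

    All groups share the same base ring lattice, edge weights, lags, and
    per-edge rewiring variates: edge e is rewired in group g iff
    ``u_e < p_g``, with a shared candidate order for the new endpoint.
    Each group's network is marginally an ordinary rewired ring at its
    own probability, but the rewiring sets are nested across groups
    (common random numbers), so the planted between-group topology
    contrast does not fluctuate with the draw — only its magnitude set by
    the ``rewiring_p`` gap.
    """
    if not (n_nodes > neighbors_k >= 2) or neighbors_k % 2:
        raise ValueError("need n_nodes > neighbors_k ≥ 2 with even k")
    for g, p in rewiring_p_by_group.items():
        if not 0 <= p <= 1:
            raise ValueError(f"rewiring_p for {g!r} must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    base_edges = [(i, (i + d) % n_nodes)
                  for d in range(1, neighbors_k // 2 + 1)
                  for i in range(n_nodes)]
    m = len(base_edges)
    u = rng.uniform(size=m)
    weights = rng.uniform(0.5, 1.0, size=m) * weight_scale
    lags = (rng.choice([-1.0, 1.0], size=m)
            * rng.uniform(np.pi / 8, 3 * np.pi / 8, size=m))
    # shared candidate order per edge for the rewired endpoint
    candidates = np.argsort(rng.random((m, n_nodes)), axis=1)

    out = {}
    for group, p in rewiring_p_by_group.items():
        adj = np.zeros((n_nodes, n_nodes))
        lag = np.zeros((n_nodes, n_nodes))
        present = set()
        for e, (i, j) in enumerate(base_edges):
            a, b = i, j
            if u[e] < p:
                for t in candidates[e]:
                    t = int(t)
                    if t != i and (min(i, t), max(i, t)) not in present \
                            and adj[i, t] == 0:
                        b = t
                        break
            if (min(a, b), max(a, b)) in present:
                continue
            present.add((min(a, b), max(a, b)))
            adj[a, b] = adj[b, a] = weights[e]
            lag[a, b], lag[b, a] = lags[e], -lags[e]
        out[group] = GroundTruthNetwork(
            n_nodes=n_nodes, adjacency=adj, lag=lag,
            topology_params={"neighbors_k": neighbors_k, "rewiring_p": p,
                             "weight_scale": weight_scale, "paired": True})
    return out


def _ou_phase(rng, n_trials, n_series, n_samples, f_center, f_spread, fs,
              drift_sd):
    """Phases of narrowband stochastic oscillators (random-walk drift)."""
    f = rng.uniform(f_center - f_spread, f_center + f_spread,
                    size=(n_trials, n_series, 1))
    inc = 2 * np.pi * f / fs + drift_sd * rng.standard_normal(
        (n_trials, n_series, n_samples))
    phase0 = rng.uniform(0, 2 * np.pi, size=(n_trials, n_series, 1))
    return phase0 + np.cumsum(inc, axis=-1)


def _ou_jitter(rng, shape, sd, tau_samples=25.0):
    """Ornstein–Uhlenbeck phase jitter with stationary sd ``sd``."""
    rho = np.exp(-1.0 / tau_samples)
    innov = np.sqrt(1 - rho ** 2) * sd * rng.standard_normal(shape)
    out = np.empty(shape)
    out[..., 0] = sd * rng.standard_normal(shape[:-1])
    for t in range(1, shape[-1]):
        out[..., t] = rho * out[..., t - 1] + innov[..., t]
    return out


def simulate_band_epochs(
    network: GroundTruthNetwork,
    band: BandDefinition,
    n_trials: int,
    n_samples: int,
    fs: float = 250.0,
    seed: int | None = None,
    amplitude_uv: float = 12.0,
    coupling_gain: float = 1.5,
    intrinsic_amp: float = 1.0,
    jitter_sd_scale: float = 0.6,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """One band's contribution to the sensor signal, (trials, ch, samples).

    Every node owns a narrowband stochastic source.  A channel mixes its
    own source with lag-shifted copies of its network neighbours'
    sources: for edge (i, j) with lag λ_ij, channel i receives
    ``cos(s_j + λ_ij + jitter)`` and channel j receives
    ``cos(s_i − λ_ij + jitter)``, each scaled by ``coupling_gain`` times
    the normalised edge weight.  Both shared copies contribute the same
    sign of the imaginary cross-spectrum, so the pair locks at the edge's
    lag; common neighbours reinforce triangle structure the same way.
    The phase jitter has standard deviation
    ``jitter_sd_scale / (0.5 + w)`` — stronger edges lock more tightly.
    Channels are normalised to RMS = ``amplitude_uv`` (µV), so the
    coupling parameters shape phase structure without moving the
    amplitude/SNR budget.
    """
    rng = rng if rng is not None else np.random.default_rng(seed)
    n = network.n_nodes
    f_c = 0.5 * (band.low_hz + band.high_hz)
    bw = band.high_hz - band.low_hz
    drift_sd = np.sqrt(np.pi * (bw / 8.0) / fs)

    source = _ou_phase(rng, n_trials, n, n_samples, f_c, bw / 4, fs,
                       drift_sd)
    x = intrinsic_amp * np.cos(source)
    power = np.full(n, intrinsic_amp ** 2 / 2.0)  # per-channel raw power

    edges = list(network.edges())
    if edges:
        w_max = max(w for _, _, w, _ in edges)
        for i, j, w, lam in edges:
            w_n = w / w_max
            amp = coupling_gain * w_n
            jit_sd = jitter_sd_scale / (0.5 + w_n)
            jit_i = _ou_jitter(rng, (n_trials, n_samples), jit_sd)
            jit_j = _ou_jitter(rng, (n_trials, n_samples), jit_sd)
            x[:, i] += amp * np.cos(source[:, j] + lam + jit_i)
            x[:, j] += amp * np.cos(source[:, i] - lam + jit_j)
            power[i] += amp ** 2 / 2.0
            power[j] += amp ** 2 / 2.0
    rms = np.sqrt(power)
    return amplitude_uv * x / rms[None, :, None]


def inject_artifacts(data: np.ndarray, artifact_rate: float,
                     rng: np.random.Generator,
                     amplitude_uv: float = 400.0,
                     width_s: float = 0.05, fs: float = 250.0) -> np.ndarray:
    """Add high-amplitude Gaussian transients to a random trial subset.

    Each selected trial gets one ±``amplitude_uv`` bump (sd ``width_s``
    seconds) on one random channel at a random latency — a caricature of
    a blink or movement artifact for the ±200 µV rejection rule.
    """
    out = data.copy()
    n_trials, n_ch, n_samp = data.shape
    hit = rng.random(n_trials) < artifact_rate
    t = np.arange(n_samp)
    for tr in np.flatnonzero(hit):
        ch = rng.integers(n_ch)
        center = rng.integers(n_samp)
        sign = rng.choice([-1.0, 1.0])
        out[tr, ch] += sign * amplitude_uv * np.exp(
            -0.5 * ((t - center) / (width_s * fs)) ** 2)
    return out


@dataclass
class CohortTruth:
    """Everything needed to regenerate a cohort and check recovery.

    ``networks[group][band]`` is the planted :class:`GroundTruthNetwork`;
    ``epochs_per_subject[group]`` is (mean, sd) of the per-subject clean
    epoch count; ``behavior_params`` holds the IES–ϕ link.  The planted
    clustering contrast is recorded explicitly in
    ``planted_clustering``.
    """

    n_subjects: dict
    networks: dict
    epochs_per_subject: dict
    behavior_params: dict
    bands: tuple
    montage_labels: tuple
    seed: int
    conditions: tuple = ("word", "pseudoword")
    noise_sd_uv: float = 4.0
    artifact_rate: float = 0.1
    planted_clustering: dict = field(default_factory=dict)

    @property
    def groups(self) -> tuple:
        return tuple(self.n_subjects)

    def subject_ids(self, group: str) -> list[str]:
        return [f"{group}{i:02d}" for i in range(self.n_subjects[group])]

    def to_json(self, path) -> None:
        """Serialise the ground truth (networks as nested lists)."""
        def net_dict(net: GroundTruthNetwork):
            return {"n_nodes": net.n_nodes,
                    "adjacency": net.adjacency.tolist(),
                    "lag": net.lag.tolist(),
                    "topology_params": net.topology_params}
        payload = {
            "n_subjects": self.n_subjects,
            "networks": {g: {b: net_dict(n) for b, n in bands.items()}
                         for g, bands in self.networks.items()},
            "epochs_per_subject": {g: list(v) for g, v in
                                   self.epochs_per_subject.items()},
            "behavior_params": self.behavior_params,
            "bands": [asdict(b) for b in self.bands],
            "montage_labels": list(self.montage_labels),
            "seed": self.seed,
            "conditions": list(self.conditions),
            "noise_sd_uv": self.noise_sd_uv,
            "artifact_rate": self.artifact_rate,
            "planted_clustering": self.planted_clustering,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


#: Study-condition defaults for the cohort generator.
DEFAULTS = {
    "n_subjects": {"control": 20, "dd": 24},
    "epochs_per_subject": {"control": (32, 5), "dd": (21, 7)},
    "rewiring_p": {"control": 0.1, "dd": 0.5},
    "neighbors_k": 6,
    "weight_scale": 1.0,
    "behavior": {
        "base_ies_ms": 2100.0,
        "slope_ies_vs_phi": -2000.0,
        "rt_noise_sd_ms": 150.0,
        "accuracy_logit_params": {"a0": 1.0, "a1": 0.0},
    },
}


def default_cohort_truth(
    seed: int,
    bands=CANONICAL_BANDS,
    montage_labels=CHANNELS_40,
    n_subjects: dict | None = None,
    epochs_per_subject: dict | None = None,
    rewiring_p: dict | None = None,
    neighbors_k: int | None = None,
    behavior: dict | None = None,
    noise_sd_uv: float = 4.0,
    artifact_rate: float = 0.1,
) -> CohortTruth:
    """Build a :class:`CohortTruth` under the default study conditions.

    One planted network per group and band (independent draws, same
    rewiring probability for every band of a group).
    """
    from .graphs import weighted_clustering

    n_subjects = dict(DEFAULTS["n_subjects"] if n_subjects is None
                      else n_subjects)
    epochs_per_subject = dict(DEFAULTS["epochs_per_subject"]
                              if epochs_per_subject is None
                              else epochs_per_subject)
    rewiring_p = dict(DEFAULTS["rewiring_p"] if rewiring_p is None
                      else rewiring_p)
    k = DEFAULTS["neighbors_k"] if neighbors_k is None else neighbors_k
    behavior = dict(DEFAULTS["behavior"] if behavior is None else behavior)

    ss = np.random.SeedSequence(seed)
    n_nodes = len(montage_labels)
    networks: dict = {g: {} for g in n_subjects}
    cs: dict = {g: [] for g in n_subjects}
    for band in bands:
        child = ss.spawn(1)[0]
        nets = make_paired_ground_truth_networks(
            n_nodes, k, rewiring_p,
            weight_scale=DEFAULTS["weight_scale"],
            seed=int(child.generate_state(1)[0] % (2 ** 31)))
        for group in n_subjects:
            networks[group][band.name] = nets[group]
            cs[group].append(weighted_clustering(nets[group].adjacency)[1])
    planted = {group: {"rewiring_p": rewiring_p[group],
                       "mean_truth_clustering": float(np.mean(cs[group]))}
               for group in n_subjects}
    return CohortTruth(
        n_subjects=n_subjects, networks=networks,
        epochs_per_subject=epochs_per_subject, behavior_params=behavior,
        bands=tuple(bands), montage_labels=tuple(montage_labels), seed=seed,
        noise_sd_uv=noise_sd_uv, artifact_rate=artifact_rate,
        planted_clustering=planted)


def cohort_truth_from_yaml(path) -> CohortTruth:
    """Load a cohort configuration from a YAML file.

    Recognised keys mirror :func:`default_cohort_truth` arguments; bands
    may be given as canonical names or ``{name, low_hz, high_hz}``
    mappings.  Unspecified keys fall back to the study-condition
    defaults.
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    kwargs = {}
    if "bands" in cfg:
        canon = {b.name: b for b in CANONICAL_BANDS}
        bands = []
        for b in cfg["bands"]:
            if isinstance(b, str):
                bands.append(canon[b])
            else:
                bands.append(BandDefinition(b["name"], b["low_hz"],
                                            b["high_hz"]))
        kwargs["bands"] = tuple(bands)
    if "montage_labels" in cfg:
        kwargs["montage_labels"] = tuple(cfg["montage_labels"])
    if "epochs_per_subject" in cfg:
        kwargs["epochs_per_subject"] = {
            g: tuple(v) for g, v in cfg["epochs_per_subject"].items()}
    for key in ("n_subjects", "rewiring_p", "neighbors_k", "behavior",
                "noise_sd_uv", "artifact_rate"):
        if key in cfg:
            kwargs[key] = cfg[key]
    return default_cohort_truth(seed=int(cfg.get("seed", 0)), **kwargs)


def _evoked_component(n_samples: int, fs: float,
                      amplitude_uv: float) -> np.ndarray:
    """Stimulus-locked waveform: damped 3 Hz oscillation from onset.

    A delta-dominant transient, like the slow components that dominate
    auditory evoked responses; it carries the event-locked energy the
    SNR criterion measures while leaving the higher analysis bands to
    the induced oscillators.
    """
    t = np.arange(n_samples) / fs
    ramp = np.clip(t / 0.05, 0.0, 1.0)
    return amplitude_uv * ramp * np.exp(-t / 0.3) * np.sin(2 * np.pi * 3 * t)


def simulate_cohort_epochs(
    truth: CohortTruth,
    montage: Montage | None = None,
    fs: float = 250.0,
    epoch_ms: float = 800.0,
    amplitude_uv: float = 8.0,
    coupling_gain: float = 1.0,
    intrinsic_amp: float = 2.0,
    jitter_sd_scale: float = 0.1,
    evoked_amp_uv: float = 45.0,
) -> dict:
    """Simulate raw (unfiltered) epochs for every subject and condition.

    Returns ``{group: {subject_id: {condition: EpochSet}}}``.  Each epoch
    sums the per-band oscillator mixtures over all bands of the truth,
    a stimulus-locked evoked component, white sensor noise, and artifact
    transients injected at the truth's ``artifact_rate``.  The evoked
    component is rank-1 (one damped-oscillation time course times a
    smooth positive sensor topography, identical across a subject's
    trials): it gives the event-locked mean the SNR criterion needs,
    while being strictly zero-lag across sensors — the kind of shared
    signal the wPLI is designed to ignore.  Fully deterministic given the
    truth's seed.
    """
    if not truth.bands:
        raise ValueError("band list is empty")
    n_samples = int(round(epoch_ms * fs / 1000.0))
    if n_samples < 100:
        raise ValueError("need ≥ 100 samples per epoch")
    if montage is None:
        montage = standard_montage(truth.montage_labels)
    if montage.n_channels != len(truth.montage_labels):
        raise ValueError("montage does not match truth montage labels")

    out: dict = {}
    for g_idx, group in enumerate(truth.groups):
        out[group] = {}
        for s_idx, subject in enumerate(truth.subject_ids(group)):
            out[group][subject] = {}
            for c_idx, condition in enumerate(truth.conditions):
                ss = np.random.SeedSequence(
                    entropy=truth.seed,
                    spawn_key=(1, g_idx, s_idx, c_idx))
                rng = np.random.default_rng(ss)
                mean, sd = truth.epochs_per_subject[group]
                n_trials = max(8, int(round(rng.normal(mean, sd))))
                topography = rng.uniform(0.8, 1.2, montage.n_channels)
                evoked = np.outer(topography,
                                  _evoked_component(n_samples, fs,
                                                    evoked_amp_uv))
                data = np.zeros((n_trials, montage.n_channels, n_samples))
                data += evoked[None, :, :]
                for band in truth.bands:
                    data += simulate_band_epochs(
                        truth.networks[group][band.name], band, n_trials,
                        n_samples, fs=fs, rng=rng,
                        amplitude_uv=amplitude_uv,
                        coupling_gain=coupling_gain,
                        intrinsic_amp=intrinsic_amp,
                        jitter_sd_scale=jitter_sd_scale)
                data += truth.noise_sd_uv * rng.standard_normal(data.shape)
                data = inject_artifacts(data, truth.artifact_rate, rng,
                                        fs=fs)
                out[group][subject][condition] = EpochSet(
                    data=data, fs=fs, channels=montage.labels,
                    subject=subject, group=group, condition=condition,
                    window_ms=epoch_ms)
    return out


def simulate_behavior(
    phi_by_subject: dict,
    behavior_params: dict,
    n_trials: int,
    seed: int | None = None,
    group_by_subject: dict | None = None,
    condition: str = "word",
) -> list[BehavioralRecord]:
    """Per-trial behavioural records with a planted IES–ϕ relationship.

    ``phi_by_subject`` maps subject id → small-world propensity ϕ ∈ [0,1].
    The subject's expected IES is ``base_ies_ms + slope_ies_vs_phi · ϕ``;
    accuracy comes from the logistic link ``p = σ(a0 + a1·ϕ)``; the mean
    correct-trial RT is then ``IES · p`` so that the IES identity holds in
    expectation.  Trial RTs are lognormal around the subject mean with
    ``rt_noise_sd_ms`` spread; correctness is Bernoulli(p).
    """
    base = behavior_params["base_ies_ms"]
    slope = behavior_params["slope_ies_vs_phi"]
    noise_sd = behavior_params["rt_noise_sd_ms"]
    logit = behavior_params["accuracy_logit_params"]
    rng = np.random.default_rng(seed)
    records: list[BehavioralRecord] = []
    for subject, phi in phi_by_subject.items():
        if not 0 <= phi <= 1:
            raise ValueError(f"ϕ out of [0,1] for {subject}")
        p_acc = 1.0 / (1.0 + np.exp(-(logit["a0"] + logit["a1"] * phi)))
        if not 0 < p_acc <= 1:
            raise ValueError("accuracy parameters imply p outside (0, 1]")
        ies = base + slope * phi
        if ies <= 0:
            raise ValueError("behavior parameters imply nonpositive IES")
        rt_mean = ies * p_acc
        if noise_sd > 0:
            sig2 = np.log(1 + (noise_sd / rt_mean) ** 2)
            mu = np.log(rt_mean) - sig2 / 2
            rts = rng.lognormal(mu, np.sqrt(sig2), size=n_trials)
        else:
            rts = np.full(n_trials, rt_mean)
        correct = rng.random(n_trials) < p_acc
        group = (group_by_subject or {}).get(subject, "")
        records.extend(
            BehavioralRecord(subject_id=subject, group=group,
                             condition=condition, rt_ms=float(rt),
                             correct=bool(c))
            for rt, c in zip(rts, correct))
    return records
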