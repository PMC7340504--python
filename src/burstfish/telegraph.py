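"""Two-state (telegraph) model of transcriptional bursting.

A promoter toggles OFF -> ON at rate ``k_on`` and ON -> OFF at rate
``k_off`` (min^-1); while ON, transcripts initiate at rate ``k_ini``;
mRNA decays at rate ``k_deg`` (0.04 min^-1 by default, the measured
*sens* decay rate). Bursts have average size ``k_ini / k_off``
(transcripts per burst) and average frequency
``(k_on^-1 + k_off^-1)^-1`` (bursts per minute).

Simulation is Gillespie's exact stochastic simulation algorithm
(SSA): trajectories start with zero mRNA and the promoter OFF, run
for a fixed number of events (10,000 by default, enough to reach
steady state), and record the final mRNA count and the event log.
The same trajectories yield nascent-RNA signal: an initiation that
happened within the elongation time ``tau_elong`` of the end of the
simulation is still on the gene; if it is younger than ``tau_probe``
(polymerase still inside the probe-binding region) it contributes
0.5 units of probe fluorescence, otherwise 1.0. Independent
simulations are randomly paired to mimic the two physically paired
alleles of a nucleus, and a pair is a *detected* transcription site
when its summed weighted nascent units reach 2.0 — the same cutoff
applied to imaging data.

The truncated chemical master equation of the same process is solved
directly (:func:`master_equation_stationary`) and serves as an
independent route against which the SSA is checked, alongside the
closed-form stationary mean and Fano factor.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit
from scipy import sparse
from scipy.sparse.linalg import spsolve

DEFAULT_K_DEG = 0.04            # min^-1, measured for sens mRNA
DEFAULT_N_EVENTS = 10_000
DEFAULT_N_PAIRS = 1000
DETECTION_UNITS = 2.0
ELONGATION_RATE_NT_PER_MIN = 1100.0

#: literature-constrained sweep bounds (min^-1)
K_INI_RANGE = (0.2, 60.0)
K_ON_RANGE = (0.008, 38.0)
K_OFF_RANGE = (0.016, 20.0)

#: elongation times (min) from the 5'-most probe site to the 3' end
TAU_ELONG_MIN = {
    "brk": 1.35,
    "dad": 2.05,
    "sens": 5.15,
    "salm": 5.30,
    "omb": 3.05,
}

EVENT_ON, EVENT_OFF, EVENT_INIT, EVENT_DEG = 0, 1, 2, 3


@dataclass(frozen=True)
class TelegraphParams:
    """Rate constants of the two-state model (all min^-1)."""

    k_on: float
    k_off: float
    k_ini: float
    k_deg: float = DEFAULT_K_DEG
    n_g_tot: int = 1

    def __post_init__(self) -> None:
        for name in ("k_on", "k_off", "k_ini", "k_deg"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_g_tot < 1:
            raise ValueError("n_g_tot must be >= 1")

    @property
    def burst_size(self) -> float:
        """Average transcripts per burst, k_ini / k_off."""
        return self.k_ini / self.k_off

    @property
    def burst_frequency(self) -> float:
        """Average bursts per minute, (k_on^-1 + k_off^-1)^-1."""
        return 1.0 / (1.0 / self.k_on + 1.0 / self.k_off)

    def replace(self, **kwargs) -> "TelegraphParams":
        d = dict(k_on=self.k_on, k_off=self.k_off, k_ini=self.k_ini,
                 k_deg=self.k_deg, n_g_tot=self.n_g_tot)
        d.update(kwargs)
        return TelegraphParams(**d)


@dataclass(frozen=True)
class BurstDescriptors:
    size: float          # transcripts per burst
    frequency: float     # bursts per minute


def burst_descriptors(params: TelegraphParams) -> BurstDescriptors:
    return BurstDescriptors(size=params.burst_size,
                            frequency=params.burst_frequency)


@dataclass(frozen=True)
class NascentTiming:
    """Elongation timing of one gene's probe set.

    ``tau_elong`` is the polymerase transit time from the 5'-most
    probe-binding site to the 3' end; ``tau_probe`` the transit time
    across the probe-binding region itself. Only ``tau_elong`` is
    tabulated per gene; ``tau_probe`` defaults to 0.8 * ``tau_elong``
    (probe sets tile most of the measured region), a documented
    assumption.
    """

    gene: str
    tau_elong: float                       # min
    tau_probe: float | None = None         # min
    elongation_rate: float = ELONGATION_RATE_NT_PER_MIN

    def __post_init__(self) -> None:
        if self.tau_elong <= 0:
            raise ValueError("tau_elong must be positive")
        if self.tau_probe is None:
            object.__setattr__(self, "tau_probe", 0.8 * self.tau_elong)
        if not (0 < self.tau_probe <= self.tau_elong):
            raise ValueError("need 0 < tau_probe <= tau_elong")

    @classmethod
    def from_gene(cls, gene: str, tau_probe: float | None = None
                  ) -> "NascentTiming":
        if gene not in TAU_ELONG_MIN:
            raise KeyError(f"no elongation time tabulated for {gene!r}; "
                           f"known genes: {sorted(TAU_ELONG_MIN)}")
        return cls(gene=gene, tau_elong=TAU_ELONG_MIN[gene],
                   tau_probe=tau_probe)


@njit(cache=True)
def _run_one(seed, k_on, k_off, k_ini, k_deg, n_g_tot, n_events,
             times, codes, mrna):
    """One SSA trajectory. Fills ``times``/``codes``/``mrna`` (length
    >= n_events; ``mrna[j]`` is the count after event j) and returns
    (n_done, final_time, final_mrna, final_ng).

    Exact SSA: waiting time ~ Exponential(1 / r_tot); the event is
    chosen with probability r_i / r_tot; initiation is enabled only
    for active gene copies.
    """
    np.random.seed(seed)
    t = 0.0
    n_m = 0
    n_g = 0                      # active copies; start OFF
    done = 0
    for _ in range(n_events):
        r_on = k_on * (n_g_tot - n_g)
        r_off = k_off * n_g
        r_ini = k_ini * n_g
        r_deg = k_deg * n_m
        r_tot = r_on + r_off + r_ini + r_deg
        if r_tot <= 0.0:
            break                # absorbing state
        t += -math.log(np.random.random()) / r_tot
        u = np.random.random() * r_tot
        if u < r_on:
            n_g += 1
            codes[done] = 0
        elif u < r_on + r_off:
            n_g -= 1
            codes[done] = 1
        elif u < r_on + r_off + r_ini:
            n_m += 1
            codes[done] = 2
        else:
            n_m -= 1
            codes[done] = 3
        times[done] = t
        mrna[done] = n_m
        done += 1
    return done, t, n_m, n_g


@njit(cache=True)
def _sample_state(times, codes, mrna, done, t_sample, tau_probe,
                  tau_elong):
    """mRNA count and weighted nascent units at time ``t_sample``."""
    # index of last event at or before t_sample
    idx = np.searchsorted(times[:done], t_sample, side="right") - 1
    n_m = mrna[idx] if idx >= 0 else 0
    w = 0.0
    for j in range(idx, -1, -1):
        age = t_sample - times[j]
        if age >= tau_elong:
            break                # older events are older still
        if codes[j] == 2:
            w += 0.5 if age < tau_probe else 1.0
    return n_m, w


@njit(cache=True)
def _run_batch(seeds, k_on, k_off, k_ini, k_deg, n_g_tot, n_events,
               tau_probe, tau_elong, sample_at_end):
    """Batch of SSA runs; returns (mRNA, weighted nascent units).

    With ``sample_at_end`` the state after the last event is recorded
    (the embedded jump chain); otherwise the state occupied at a
    uniformly drawn time in the second half of the trajectory, which
    converges to the time-stationary master-equation distribution.
    """
    n = len(seeds)
    mature = np.zeros(n, dtype=np.int64)
    nascent = np.zeros(n, dtype=np.float64)
    times = np.empty(n_events, dtype=np.float64)
    codes = np.empty(n_events, dtype=np.int8)
    mrna = np.empty(n_events, dtype=np.int64)
    for i in range(n):
        done, t_end, n_m, _ = _run_one(
            seeds[i], k_on, k_off, k_ini, k_deg, n_g_tot, n_events,
            times, codes, mrna)
        if done == 0:
            mature[i] = 0
            nascent[i] = 0.0
            continue
        if sample_at_end:
            t_sample = t_end
        else:
            t_sample = t_end * (0.5 + 0.5 * np.random.random())
        n_s, w = _sample_state(times, codes, mrna, done, t_sample,
                               tau_probe, tau_elong)
        mature[i] = n_s
        nascent[i] = w
    return mature, nascent


@njit(cache=True)
def _occupation_batch(seeds, k_on, k_off, k_ini, k_deg, n_g_tot,
                      n_events, n_max):
    """Time-weighted occupancy histogram of the mRNA count over the
    second half of each trajectory, summed across runs."""
    hist = np.zeros(n_max + 1, dtype=np.float64)
    times = np.empty(n_events, dtype=np.float64)
    codes = np.empty(n_events, dtype=np.int8)
    mrna = np.empty(n_events, dtype=np.int64)
    for i in range(len(seeds)):
        done, t_end, _, _ = _run_one(
            seeds[i], k_on, k_off, k_ini, k_deg, n_g_tot, n_events,
            times, codes, mrna)
        if done < 2:
            continue
        t_half = 0.5 * t_end
        j0 = np.searchsorted(times[:done], t_half, side="right") - 1
        if j0 < 0:
            j0 = 0
        for j in range(j0, done):
            t0 = times[j] if times[j] > t_half else t_half
            t1 = times[j + 1] if j + 1 < done else t_end
            if t1 <= t0:
                continue
            state = mrna[j]
            if state <= n_max:
                hist[state] += t1 - t0
    return hist


@dataclass
class Trajectory:
    """Event log of a single SSA run."""

    params: TelegraphParams
    times: np.ndarray            # event times (min)
    events: np.ndarray           # event codes (EVENT_*)
    final_time: float
    final_mrna: int
    final_active: int
    seed: int
    absorbed: bool = False

    @property
    def n_events(self) -> int:
        return len(self.times)

    @property
    def initiation_times(self) -> np.ndarray:
        return self.times[self.events == EVENT_INIT]

    def mrna_trace(self) -> np.ndarray:
        """mRNA count after each event."""
        delta = np.where(self.events == EVENT_INIT, 1,
                         np.where(self.events == EVENT_DEG, -1, 0))
        return np.cumsum(delta)


def gillespie_run(params: TelegraphParams,
                  n_events: int = DEFAULT_N_EVENTS,
                  seed: int = 0) -> Trajectory:
    """Run one exact SSA trajectory of ``n_events`` events.

    Starts with zero mRNA and the promoter OFF. If the system hits an
    absorbing state (all propensities zero, e.g. ``k_on = 0`` with the
    promoter OFF) the run terminates early with a warning.
    """
    if n_events < 1:
        raise ValueError("n_events must be >= 1")
    times = np.empty(n_events, dtype=np.float64)
    codes = np.empty(n_events, dtype=np.int8)
    mrna = np.empty(n_events, dtype=np.int64)
    done, t, n_m, n_g = _run_one(
        np.uint32(seed) if seed >= 0 else np.uint32(abs(seed)),
        params.k_on, params.k_off, params.k_ini, params.k_deg,
        params.n_g_tot, n_events, times, codes, mrna)
    absorbed = done < n_events
    if absorbed:
        warnings.warn(
            f"SSA reached an absorbing state after {done} events "
            f"(all reaction rates zero); trajectory truncated",
            stacklevel=2)
    return Trajectory(params=params, times=times[:done].copy(),
                      events=codes[:done].copy(), final_time=float(t),
                      final_mrna=int(n_m), final_active=int(n_g),
                      seed=seed, absorbed=absorbed)


def count_nascent(trajectory: Trajectory, timing: NascentTiming) -> float:
    """Weighted nascent units on one allele at the end of a run.

    An initiation of age ``a = T - t`` contributes 0.5 units when
    ``a < tau_probe`` (probe region partially transcribed), 1.0 when
    ``tau_probe <= a < tau_elong`` (all probe sites transcribed, still
    on the gene), and 0 once ``a >= tau_elong`` (mature, released).
    The 0.5 is the deterministic ensemble expectation for partially
    transcribed probe regions.
    """
    ages = trajectory.final_time - trajectory.initiation_times
    w = np.where(ages < timing.tau_probe, 0.5,
                 np.where(ages < timing.tau_elong, 1.0, 0.0))
    return float(w.sum())


def normalized_site_signal(transcribed_probe_sites: float,
                           probe_sites_per_mrna: float = 6.0) -> float:
    """Normalized signal of a site snapshot: total transcribed
    probe-binding sites divided by the sites per mature mRNA (e.g. 12
    transcribed sites at 6 per mRNA = 2.0 units, right at the
    detection cutoff)."""
    if probe_sites_per_mrna <= 0:
        raise ValueError("probe_sites_per_mrna must be positive")
    return transcribed_probe_sites / probe_sites_per_mrna


def _derive_seeds(seed: int, n: int) -> np.ndarray:
    return np.random.SeedSequence(seed).generate_state(n).astype(np.uint32)


@dataclass
class SimBatch:
    """Per-allele outcomes of a batch of independent simulations."""

    params: TelegraphParams
    timing: NascentTiming | None
    mature: np.ndarray           # final mRNA count per simulation
    nascent: np.ndarray          # weighted nascent units per simulation
    seed: int


def simulate_batch(params: TelegraphParams,
                   timing: NascentTiming | None = None,
                   n_sims: int = 1000,
                   n_events: int = DEFAULT_N_EVENTS,
                   seed: int = 0,
                   record: str = "stationary") -> SimBatch:
    """Run ``n_sims`` independent SSA trajectories.

    Per-run seeds derive deterministically from the root seed, so any
    slice of the batch is reproducible independent of batch size.
    When ``timing`` is None nascent units are reported as zero.

    ``record`` selects the per-run outcome: ``"stationary"`` (default)
    records the state occupied at a uniformly drawn time in the
    second half of the trajectory, an asymptotically exact sample of
    the time-stationary (master-equation) distribution; ``"end"``
    records the state immediately after the last event, which samples
    the embedded jump chain and over-weights high-propensity states.
    """
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    if record not in ("stationary", "end"):
        raise ValueError("record must be 'stationary' or 'end'")
    tau_probe = timing.tau_probe if timing else 0.0
    tau_elong = timing.tau_elong if timing else 0.0
    seeds = _derive_seeds(seed, n_sims)
    mature, nascent = _run_batch(
        seeds, params.k_on, params.k_off, params.k_ini, params.k_deg,
        params.n_g_tot, n_events, tau_probe, tau_elong,
        record == "end")
    return SimBatch(params=params, timing=timing, mature=mature,
                    nascent=nascent, seed=seed)


@dataclass
class PairedOutcomes:
    """Randomly paired simulations mimicking the two alleles of a cell."""

    mature: np.ndarray           # summed mRNA per pair
    nascent: np.ndarray          # summed weighted nascent units per pair
    detected: np.ndarray         # nascent >= 2.0 units
    pairing: np.ndarray          # (n_pairs, 2) indices into the batch

    @property
    def n_pairs(self) -> int:
        return len(self.mature)

    @property
    def fraction_detected(self) -> float:
        return float(self.detected.mean()) if len(self.detected) else 0.0

    def median_nascent_detected(self) -> float:
        """Median nascent units among detected pairs (NaN if none)."""
        if not self.detected.any():
            return float("nan")
        return float(np.median(self.nascent[self.detected]))


def pair_alleles(batch: SimBatch, seed: int = 0,
                 detection_units: float = DETECTION_UNITS) -> PairedOutcomes:
    """Randomly pair simulations into two-allele virtual cells.

    The pairing is a random disjoint matching; an odd simulation
    count drops one with a warning. A pair is a detected
    transcription site when its summed weighted nascent units are
    >= ``detection_units`` (2.0, the cutoff applied to image data —
    the boundary is inclusive).
    """
    n = len(batch.mature)
    if n < 2:
        raise ValueError("need at least 2 simulations to pair")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    if n % 2:
        warnings.warn("odd number of simulations: dropping one for "
                      "pairing", stacklevel=2)
        order = order[:-1]
    pairing = order.reshape(-1, 2)
    mature = batch.mature[pairing].sum(axis=1)
    nascent = batch.nascent[pairing].sum(axis=1)
    return PairedOutcomes(mature=mature, nascent=nascent,
                          detected=nascent >= detection_units,
                          pairing=pairing)


_SWEEP_BOUNDS = {"k_ini": K_INI_RANGE, "k_on": K_ON_RANGE,
                 "k_off": K_OFF_RANGE}


def sweep(param_name: str, values, base: TelegraphParams,
          timing: NascentTiming, n_pairs: int = DEFAULT_N_PAIRS,
          n_events: int = DEFAULT_N_EVENTS, seed: int = 0,
          enforce_bounds: bool = True) -> pd.DataFrame:
    """Sweep one rate parameter; per value, paired-simulation statistics.

    Varying ``k_ini`` at fixed ``k_on``/``k_off`` modulates burst size
    alone; varying ``k_on`` at fixed ``k_ini``/``k_off`` modulates
    burst frequency alone. Each value runs ``2 * n_pairs`` simulations
    and reports the fraction of pairs detected (weighted nascent units
    >= 2.0) and the median nascent units among detected pairs.
    """
    if param_name not in _SWEEP_BOUNDS:
        raise ValueError(f"unknown sweep parameter {param_name!r}")
    if n_pairs < 100:
        raise ValueError("n_pairs must be >= 100 for stable fractions")
    lo, hi = _SWEEP_BOUNDS[param_name]
    values = np.asarray(list(values), dtype=float)
    if enforce_bounds and (values.min() < lo or values.max() > hi):
        raise ValueError(
            f"{param_name} sweep values must lie within the "
            f"literature-constrained range [{lo}, {hi}] /min")
    rows = []
    root = np.random.SeedSequence(seed).spawn(len(values))
    for v, ss in zip(values, root):
        p = base.replace(**{param_name: float(v)})
        s1, s2 = ss.generate_state(2) % (2 ** 31)
        batch = simulate_batch(p, timing, n_sims=2 * n_pairs,
                               n_events=n_events, seed=int(s1))
        paired = pair_alleles(batch, seed=int(s2))
        rows.append({
            "param": param_name, "value": float(v),
            "k_on": p.k_on, "k_off": p.k_off, "k_ini": p.k_ini,
            "burst_size": p.burst_size,
            "burst_frequency": p.burst_frequency,
            "fraction_detected": paired.fraction_detected,
            "median_nascent_detected": paired.median_nascent_detected(),
            "n_pairs": paired.n_pairs,
        })
    return pd.DataFrame(rows)


def rates_for_burst(size: float, frequency: float,
                    k_deg: float = DEFAULT_K_DEG,
                    kon_koff_ratio: float = 1.0) -> TelegraphParams:
    """Map a (burst size, burst frequency) pair to rate constants.

    With ``rho = k_on / k_off`` fixed:
    ``k_off = frequency * (1 + rho) / rho``, ``k_on = rho * k_off``,
    ``k_ini = size * k_off``. The ratio policy is configurable; the
    default rho = 1 splits ON and OFF dwell times evenly.
    """
    if size <= 0 or frequency <= 0:
        raise ValueError("burst size and frequency must be positive")
    k_off = frequency * (1.0 + kon_koff_ratio) / kon_koff_ratio
    k_on = kon_koff_ratio * k_off
    k_ini = size * k_off
    return TelegraphParams(k_on=k_on, k_off=k_off, k_ini=k_ini,
                           k_deg=k_deg)


def phase_diagram(burst_sizes, burst_frequencies,
                  timing: NascentTiming,
                  k_deg: float = DEFAULT_K_DEG,
                  n_pairs: int = DEFAULT_N_PAIRS,
                  n_events: int = DEFAULT_N_EVENTS,
                  seed: int = 0,
                  kon_koff_ratio: float = 1.0,
                  enforce_bounds: bool = True) -> pd.DataFrame:
    """Detection fraction over a (burst size, burst frequency) grid.

    Grid points whose implied rates fall outside the
    literature-constrained bounds are marked infeasible (NaN). Rows:
    burst_size, burst_frequency, fraction_detected,
    median_nascent_detected, feasible.
    """
    sizes = np.asarray(list(burst_sizes), dtype=float)
    freqs = np.asarray(list(burst_frequencies), dtype=float)
    rows = []
    seqs = np.random.SeedSequence(seed).spawn(len(sizes) * len(freqs))
    k = 0
    for f in freqs:
        for s in sizes:
            p = rates_for_burst(s, f, k_deg, kon_koff_ratio)
            feasible = (K_ON_RANGE[0] <= p.k_on <= K_ON_RANGE[1]
                        and K_OFF_RANGE[0] <= p.k_off <= K_OFF_RANGE[1]
                        and K_INI_RANGE[0] <= p.k_ini <= K_INI_RANGE[1])
            row = {"burst_size": s, "burst_frequency": f,
                   "k_on": p.k_on, "k_off": p.k_off, "k_ini": p.k_ini,
                   "feasible": feasible,
                   "fraction_detected": float("nan"),
                   "median_nascent_detected": float("nan")}
            if feasible or not enforce_bounds:
                s1, s2 = seqs[k].generate_state(2) % (2 ** 31)
                batch = simulate_batch(p, timing, n_sims=2 * n_pairs,
                                       n_events=n_events, seed=int(s1))
                paired = pair_alleles(batch, seed=int(s2))
                row["fraction_detected"] = paired.fraction_detected
                row["median_nascent_detected"] = \
                    paired.median_nascent_detected()
            rows.append(row)
            k += 1
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------
# independent route: truncated chemical master equation
# ---------------------------------------------------------------------

def telegraph_mean(params: TelegraphParams) -> float:
    """Stationary mean mRNA: N_g_tot * (k_on/(k_on+k_off)) * k_ini/k_deg."""
    p_on = params.k_on / (params.k_on + params.k_off)
    return params.n_g_tot * p_on * params.k_ini / params.k_deg


def telegraph_fano(params: TelegraphParams) -> float:
    """Stationary Fano factor of the telegraph model.

    ``1 + k_ini k_off / ((k_on + k_off)(k_deg + k_on + k_off))``;
    independent gene copies leave the Fano factor unchanged. Equals 1
    in the constitutive (always-ON) limit.
    """
    s = params.k_on + params.k_off
    return 1.0 + (params.k_ini * params.k_off) / (s * (params.k_deg + s))


def master_equation_stationary(params: TelegraphParams,
                               n_max: int | None = None) -> np.ndarray:
    """Stationary mRNA distribution from the truncated master equation.

    The state space is (N_m, N_g) with N_m <= n_max and
    N_g <= N_g_tot; transitions are initiation (rate k_ini * N_g),
    decay (k_deg * N_m), activation (k_on * (N_g_tot - N_g)) and
    inactivation (k_off * N_g). The stationary distribution solves
    pi Q = 0 with pi summing to one; the returned array is the
    marginal over N_m. ``n_max`` defaults to mean + 12 sd.
    """
    if n_max is None:
        mean = telegraph_mean(params)
        sd = math.sqrt(max(telegraph_fano(params) * mean, 1.0))
        n_max = max(int(math.ceil(mean + 12 * sd)), 30)
    ng_states = params.n_g_tot + 1
    n_states = (n_max + 1) * ng_states

    def sid(nm: int, ng: int) -> int:
        return nm * ng_states + ng

    rows, cols, vals = [], [], []

    def add(i, j, rate):
        rows.append(i)
        cols.append(j)
        vals.append(rate)

    for nm in range(n_max + 1):
        for ng in range(ng_states):
            i = sid(nm, ng)
            out = 0.0
            if nm < n_max and ng > 0:
                r = params.k_ini * ng
                add(sid(nm + 1, ng), i, r)
                out += r
            if nm > 0:
                r = params.k_deg * nm
                add(sid(nm - 1, ng), i, r)
                out += r
            if ng < params.n_g_tot:
                r = params.k_on * (params.n_g_tot - ng)
                add(sid(nm, ng + 1), i, r)
                out += r
            if ng > 0:
                r = params.k_off * ng
                add(sid(nm, ng - 1), i, r)
                out += r
            add(i, i, -out)

    Q = sparse.csr_matrix((vals, (rows, cols)),
                          shape=(n_states, n_states))
    # replace the last balance equation with normalization
    A = sparse.lil_matrix(Q)
    A[-1, :] = 1.0
    b = np.zeros(n_states)
    b[-1] = 1.0
    pi = spsolve(sparse.csr_matrix(A), b)
    pi = np.clip(pi, 0.0, None)
    pi /= pi.sum()
    return pi.reshape(n_max + 1, ng_states).sum(axis=1)


def total_variation(p: np.ndarray, q: np.ndarray) -> float:
    """Total-variation distance between two discrete distributions."""
    n = max(len(p), len(q))
    pp = np.zeros(n)
    qq = np.zeros(n)
    pp[:len(p)] = p
    qq[:len(q)] = q
    return 0.5 * float(np.abs(pp - qq).sum())


def occupation_distribution(params: TelegraphParams,
                            n_runs: int = 10_000,
                            n_events: int = DEFAULT_N_EVENTS,
                            seed: int = 0,
                            n_max: int | None = None) -> np.ndarray:
    """Empirical stationary mRNA distribution from SSA trajectories.

    The ergodic estimator: the time the process spends in each mRNA
    state over the second half of each trajectory (first half
    discarded as burn-in), pooled across runs and normalized. This
    is the empirical counterpart of the master-equation stationary
    distribution.
    """
    if n_max is None:
        mean = telegraph_mean(params)
        sd = math.sqrt(max(telegraph_fano(params) * mean, 1.0))
        n_max = max(int(math.ceil(mean + 12 * sd)), 30)
    seeds = _derive_seeds(seed, n_runs)
    hist = _occupation_batch(seeds, params.k_on, params.k_off,
                             params.k_ini, params.k_deg,
                             params.n_g_tot, n_events, n_max)
    total = hist.sum()
    if total <= 0:
        raise RuntimeError("no occupancy accumulated (absorbing runs?)")
    return hist / total


def empirical_distribution(counts: np.ndarray,
                           n_max: int | None = None) -> np.ndarray:
    """Empirical probability mass function of integer counts."""
    counts = np.asarray(counts, dtype=int)
    hi = int(counts.max()) if n_max is None else n_max
    pmf = np.bincount(counts, minlength=hi + 1).astype(float)
    return pmf / pmf.sum()


__all__ = [
    "TelegraphParams", "BurstDescriptors", "NascentTiming",
    "Trajectory", "SimBatch", "PairedOutcomes",
    "gillespie_run", "simulate_batch", "count_nascent",
    "normalized_site_signal", "pair_alleles", "sweep",
    "phase_diagram", "rates_for_burst", "burst_descriptors",
    "telegraph_mean", "telegraph_fano", "master_equation_stationary",
    "total_variation", "empirical_distribution",
    "occupation_distribution",
    "TAU_ELONG_MIN", "DETECTION_UNITS", "DEFAULT_K_DEG",
    "DEFAULT_N_EVENTS", "K_INI_RANGE", "K_ON_RANGE", "K_OFF_RANGE",
    "ELONGATION_RATE_NT_PER_MIN",
    "EVENT_ON", "EVENT_OFF", "EVENT_INIT", "EVENT_DEG",
]
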