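"""Reproducible experiment runners for every stimulus battery.

Each runner builds a network, generates the stimulus protocol, simulates
every condition (oddball pairs are always presented twice, with the
frequencies swapped and the role pattern preserved), and reduces the spike
records to SSA summaries.  Runs are pure functions of an
:class:`ExperimentSpec`; per-condition seeds are spawned deterministically
from the root seed.

Scaling: the full-scale network (48 units per AdEx population, 96 or 144
input sub-populations, 800-1000-tone sequences) is expensive, so every
runner accepts scaled-down sizes.  When the sub-population count is
reduced, the input pathway weights are multiplied by
``full_n_subpop / n_subpop`` so each B unit receives the same total
synaptic conductance; population counts otherwise change nothing about
the condition structure.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import params as P
from .analysis import (
    SIResult,
    count_spikes,
    fit_exponential,
    history_conditioned,
    ks_test,
    si_from_tables,
)
from .network import ArchitectureSpec, Network, build_network, simulate
from .stimuli import (
    DEVIANT,
    STANDARD,
    MarkovSpec,
    ToneSequence,
    TuningSpec,
    make_grid_sequence,
    make_many_standards,
    make_markov,
    make_oddball,
    oddball_pair,
)

FULL_N_B = 48
FULL_N_SUBPOP = {"two_tone": 96, "multi_tone": 144}
FULL_IN_DEGREE = 16

EXPERIMENTS = (
    "oddball_grid",
    "isi_sweep",
    "duration_sweep",
    "markov_sweep",
    "grid_modes",
    "many_standards",
    "calibration",
)


@dataclass(frozen=True)
class ExperimentSpec:
    """A fully deterministic description of one experiment run.

    The defaults are the scaled-down study conditions (8 B units, 24
    sub-populations, 200-tone sequences); :meth:`full_scale` restores the
    full population and tone counts.
    """

    experiment: str = "oddball_grid"
    architecture: str = "ABC"
    n_b: int = 8
    n_subpop: int = 24
    n_tones: int = 200
    delta_f: tuple = (0.25, 0.5, 1.0)
    p_values: tuple = (0.1, 0.3)
    s_values: tuple = (1.0 / 3.0, 2.0 / 3.0, 1.0)
    isi_values: tuple = (250.0, 500.0, 1000.0)
    duration_values: tuple = (50.0, 100.0)
    iai_ms: float = 500.0
    duration_ms: float = 100.0
    window_ms: tuple | None = None
    task: str = "two_tone"
    n_replicates: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.experiment not in EXPERIMENTS:
            raise ValueError(f"experiment must be one of {EXPERIMENTS}")
        if self.n_tones < 1 or self.n_b < 1:
            raise ValueError("population and tone counts must be >= 1")

    @classmethod
    def full_scale(cls, experiment: str, **kw) -> "ExperimentSpec":
        task = kw.pop("task", "two_tone")
        return cls(
            experiment=experiment,
            n_b=FULL_N_B,
            n_subpop=FULL_N_SUBPOP[task],
            n_tones=1000 if experiment == "markov_sweep" else 800,
            task=task,
            **kw,
        )

    def config_hash(self) -> str:
        blob = yaml.safe_dump(self.__dict__, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def child_seed(self, *labels) -> int:
        """Deterministic per-condition seed derived from the root seed."""
        h = hashlib.sha256(
            (self.config_hash() + "|" + "|".join(map(str, labels))).encode()
        ).digest()
        return int.from_bytes(h[:4], "little") % 2**31


def make_tuning(spec: ExperimentSpec) -> TuningSpec:
    d = P.load_defaults()["tuning"][spec.task]
    return TuningSpec(
        n_subpop=spec.n_subpop,
        span_octaves=float(d["span_octaves"]),
        spont_hz=float(d["spont_hz"]),
        max_hz=float(d["max_hz"]),
        bandwidth_oct=float(d["bandwidth_oct"]),
    )


def make_network(spec: ExperimentSpec, weight_overrides: dict | None = None) -> Network:
    """Build the network for an experiment, compensating scaled input counts.

    ``weight_overrides`` maps pathway name -> multiplicative factor on the
    calibrated nominal weight (used by the calibration sweep and the
    zero-weight controls).
    """
    defaults = P.load_defaults()
    comp = FULL_N_SUBPOP[spec.task] / spec.n_subpop
    overrides = weight_overrides or {}
    pathways = {}
    for name in ("A_B", "A_C", "C_B", "B_D"):
        params = P.synapse_from_defaults(name, defaults)
        w = params.weight_nS
        if name in ("A_B", "A_C"):
            w *= comp
        elif name == "B_D":
            w *= FULL_N_B / spec.n_b
        w *= overrides.get(name, 1.0)
        pathways[name] = P.replace(params, weight_nS=w)
    arch_spec = ArchitectureSpec(
        architecture=spec.architecture,
        n_b=spec.n_b,
        n_subpop=spec.n_subpop,
        inhib_in_degree=min(FULL_IN_DEGREE, spec.n_b),
        pathways=pathways,
        seed=spec.child_seed("network"),
    )
    return build_network(arch_spec)


def _simulate_pair(
    network: Network,
    pair: tuple[ToneSequence, ToneSequence],
    tuning: TuningSpec,
    spec: ExperimentSpec,
    *labels,
) -> SIResult:
    seq, twin = pair
    rec1 = simulate(network, seq, tuning, seed=spec.child_seed(*labels, "sim1"))
    rec2 = simulate(network, twin, tuning, seed=spec.child_seed(*labels, "sim2"))
    t1 = count_spikes(rec1, seq, spec.window_ms, n_units=network.spec.n_b)
    t2 = count_spikes(rec2, twin, spec.window_ms, n_units=network.spec.n_b)
    return si_from_tables(t1, t2)


def _mean_counts(table: pd.DataFrame) -> tuple[float, float]:
    s = table[table.role == STANDARD]["count"].mean()
    d = table[table.role == DEVIANT]["count"].mean()
    return float(s), float(d)


def run_oddball_grid(spec: ExperimentSpec) -> pd.DataFrame:
    """Median SI per (delta_f, p) condition plus the equiprobable control.

    Returns one row per condition with the population median neuron-specific
    SI, a significance p-value, and the mean standard/deviant counts.

    With ``n_replicates`` > 1 each condition is probed with that many
    independent sequence-pair realizations and the reported statistic is
    the median over per-replicate median SIs, tested against zero with a
    signed-rank test across replicates.  Replicates are statistically
    independent samples, unlike the units within one run, which all share
    a single role-pattern realization; the replicate-level test is
    therefore the honest test at small scale (see the methods note).
    """
    network = make_network(spec)
    tuning = make_tuning(spec)
    conditions = [(df, p) for df in spec.delta_f for p in spec.p_values]
    conditions.append((max(spec.delta_f), 0.5))  # control
    rows = []
    for df, p in conditions:
        rep_medians = []
        last = None
        for rep in range(spec.n_replicates):
            rng = np.random.default_rng(spec.child_seed("stim", df, p, rep))
            pair = make_oddball(
                oddball_pair(df), p, spec.n_tones, spec.iai_ms, spec.duration_ms, rng
            )
            last = _simulate_pair(network, pair, tuning, spec, "oddball", df, p, rep)
            rep_medians.append(last.median_si)
        if spec.n_replicates > 1:
            med = float(np.median(rep_medians))
            from scipy import stats

            p_value = (
                float(stats.wilcoxon(rep_medians).pvalue)
                if np.any(np.asarray(rep_medians) != 0)
                else 1.0
            )
        else:
            med = last.median_si
            p_value = last.signed_rank_p
        rows.append(
            {
                "delta_f": df,
                "p": p,
                "control": p == 0.5,
                "median_si": med,
                "signed_rank_p": p_value,
                "n_replicates": spec.n_replicates,
                "mean_d": last.per_unit[["d1", "d2"]].mean().mean(),
                "mean_s": last.per_unit[["s1", "s2"]].mean().mean(),
                "n_units": last.n_units,
            }
        )
    return pd.DataFrame(rows)


def run_isi_sweep(spec: ExperimentSpec) -> dict:
    """SI versus inter-onset interval at fixed (delta_f, p), with an
    exponential-decay fit for read-off at arbitrary ISI."""
    if len(spec.isi_values) < 3:
        raise ValueError("need at least 3 ISI values")
    network = make_network(spec)
    tuning = make_tuning(spec)
    df = max(spec.delta_f)
    p = min(spec.p_values)
    rows = []
    for isi in spec.isi_values:
        si_reps = []
        for rep in range(spec.n_replicates):
            rng = np.random.default_rng(spec.child_seed("stim", isi, rep))
            pair = make_oddball(
                oddball_pair(df), p, spec.n_tones, isi,
                min(spec.duration_ms, isi / 2), rng,
            )
            res = _simulate_pair(network, pair, tuning, spec, "isi", isi, rep)
            si_reps.append(res.median_si)
        rows.append(
            {
                "isi_ms": isi,
                "median_si": float(np.mean(si_reps)),
                "sem": float(np.std(si_reps) / np.sqrt(len(si_reps)))
                if len(si_reps) > 1
                else np.nan,
            }
        )
    table = pd.DataFrame(rows)
    fit = fit_exponential(
        table["isi_ms"].to_numpy(), table["median_si"].to_numpy(), form="decay"
    )
    return {"table": table, "fit": fit, "read_off": fit}


def run_duration_sweep(spec: ExperimentSpec) -> pd.DataFrame:
    """SI over the (ISI, tone duration) grid.

    Cells with equal offset-to-onset gap (ISI minus duration) share a
    recovery time; the returned frame carries that gap for the
    iso-recovery diagnostics.
    """
    network = make_network(spec)
    tuning = make_tuning(spec)
    df = max(spec.delta_f)
    p = min(spec.p_values)
    rows = []
    for isi in spec.isi_values:
        for dur in spec.duration_values:
            if dur >= isi:
                continue
            rng = np.random.default_rng(spec.child_seed("stim", isi, dur))
            pair = make_oddball(
                oddball_pair(df), p, spec.n_tones, isi, dur, rng
            )
            res = _simulate_pair(network, pair, tuning, spec, "dur", isi, dur)
            rows.append(
                {
                    "isi_ms": isi,
                    "duration_ms": dur,
                    "recovery_gap_ms": isi - dur,
                    "median_si": res.median_si,
                }
            )
    return pd.DataFrame(rows)


def run_markov_sweep(spec: ExperimentSpec) -> pd.DataFrame:
    """Mean deviant/standard counts and SI per (p, s) Markov condition."""
    network = make_network(spec)
    tuning = make_tuning(spec)
    df = max(spec.delta_f)
    rows = []
    for p in spec.p_values:
        for s in spec.s_values:
            if not 0 < s <= 1:
                continue
            mspec = MarkovSpec(
                p=p, s=s, n_tones=spec.n_tones,
                freq_pair=oddball_pair(df),
                iai_ms=spec.iai_ms, duration_ms=spec.duration_ms,
            )
            rng = np.random.default_rng(spec.child_seed("stim", p, s))
            seq, twin = make_markov(mspec, rng)
            rec1 = simulate(network, seq, tuning, seed=spec.child_seed("mk", p, s, 1))
            rec2 = simulate(network, twin, tuning, seed=spec.child_seed("mk", p, s, 2))
            t1 = count_spikes(rec1, seq, spec.window_ms, n_units=spec.n_b)
            t2 = count_spikes(rec2, twin, spec.window_ms, n_units=spec.n_b)
            res = si_from_tables(t1, t2)
            s1, d1 = _mean_counts(t1)
            s2, d2 = _mean_counts(t2)
            rows.append(
                {
                    "p": p,
                    "s": s,
                    "median_si": res.median_si,
                    "signed_rank_p": res.signed_rank_p,
                    "mean_d": (d1 + d2) / 2,
                    "mean_s": (s1 + s2) / 2,
                }
            )
    return pd.DataFrame(rows)


def run_grid_modes(spec: ExperimentSpec, n_freq: int = 10, n_rep: int = 10) -> dict:
    """Block / sequential / random grids, with and without depression.

    Returns per-mode per-(unit, tone) count tables, grand means, and the
    pairwise KS p-values between mode count distributions.
    """
    network = make_network(spec)
    network_nodep = network.with_depression("A_B", False)
    tuning = make_tuning(spec)
    spacing = tuning.span_octaves / n_freq
    out: dict = {"counts": {}, "grand_mean": {}, "ks": {}}
    for label, net in (("depressing", network), ("non_depressing", network_nodep)):
        per_unit_means = {}
        for mode in ("block", "sequential", "random"):
            rng = np.random.default_rng(spec.child_seed("stim", mode))
            seq = make_grid_sequence(
                mode, n_freq, n_rep, spacing, spec.iai_ms, spec.duration_ms, rng
            )
            rec = simulate(
                net, seq, tuning, seed=spec.child_seed("grid", label, mode)
            )
            tab = count_spikes(rec, seq, spec.window_ms, n_units=spec.n_b)
            out["counts"][(label, mode)] = tab
            per_unit_means[mode] = tab.groupby("unit")["count"].mean()
            out["grand_mean"][(label, mode)] = float(tab["count"].mean())
        for a, b in (("block", "sequential"), ("sequential", "random"), ("block", "random")):
            if spec.n_b >= 5:
                out["ks"][(label, a, b)] = ks_test(per_unit_means[a], per_unit_means[b])
            else:
                out["ks"][(label, a, b)] = np.nan  # too few units for the test
    return out


def run_many_standards(
    spec: ExperimentSpec,
    positions: tuple | None = None,
    deviant_indices: tuple | None = None,
) -> pd.DataFrame:
    """Single-standard versus many-standards deviant responses (ABD).

    For each deviant position: mean spike counts for the standard, the true
    (oddball) deviant and the control (many-standards) deviant, in both
    populations B and D.  The default geometry is the wide-spacing layout
    on the multi-tone (3-octave) task: six positions spaced 0.5 octaves
    apart, deviants in the upper half, the single standard mirrored about
    the centre, so adjacent channels are nearly independent (the spacing
    equals the tuning bandwidth; overlap ~6%).
    """
    if spec.architecture != "ABD":
        raise ValueError("the many-standards experiment targets the ABD model")
    if positions is None:
        positions = tuple(np.round((np.arange(6) - 2.5) * 0.5, 6))
    if deviant_indices is None:
        deviant_indices = tuple(range(len(positions) // 2, len(positions)))
    network = make_network(spec)
    tuning = make_tuning(spec)
    n_other = len(positions) - 1
    # largest feasible tone count <= spec.n_tones with exact balance at p=0.1
    n_tones = spec.n_tones - (spec.n_tones - spec.n_tones // 10) % n_other
    while (n_tones - n_tones // 10) % n_other or n_tones % 10:
        n_tones -= 1
    rows = []
    for di in deviant_indices:
        rng = np.random.default_rng(spec.child_seed("stim", di))
        odd, ctl = make_many_standards(
            positions, di, n_tones, 0.1, rng,
            iai_ms=spec.iai_ms, duration_ms=spec.duration_ms,
        )
        si_std = len(positions) - 1 - di
        delta_f = abs(positions[di] - positions[si_std])
        row = {"deviant_index": di, "delta_f": round(delta_f, 6)}
        for label, seq in (("oddball", odd), ("control", ctl)):
            rec = simulate(
                network, seq, tuning, seed=spec.child_seed("ms", di, label)
            )
            for pop in ("B", "D"):
                tab = count_spikes(
                    rec, seq, spec.window_ms, population=pop, n_units=spec.n_b
                )
                s, d = _mean_counts(tab)
                row[f"dev_{label}_{pop}"] = d
                if label == "oddball":
                    row[f"std_{pop}"] = s
        rows.append(row)
    df = pd.DataFrame(rows)
    for pop in ("B", "D"):
        df[f"excess_{pop}"] = df[f"dev_oddball_{pop}"] - df[f"dev_control_{pop}"]
    return df


def crossing_point(delta_f, excess) -> float | None:
    """Piecewise-linear estimate of where the single-standard and
    many-standards deviant curves intersect (excess changes sign)."""
    x = np.asarray(delta_f, float)
    y = np.asarray(excess, float)
    order = np.argsort(x)
    x, y = x[order], y[order]
    for k in range(len(x) - 1):
        if y[k] == 0:
            return float(x[k])
        if y[k] * y[k + 1] < 0:
            t = y[k] / (y[k] - y[k + 1])
            return float(x[k] + t * (x[k + 1] - x[k]))
    return None


def run_calibration(
    spec: ExperimentSpec,
    pathway: str = "A_B",
    factors: tuple = (0.5, 1.0, 2.0),
) -> pd.DataFrame:
    """Sweep one pathway's weight (holding the rest fixed) and record the
    median SI in the high-SSA oddball condition — the workflow used to
    select the shipped default weights."""
    tuning = make_tuning(spec)
    df = max(spec.delta_f)
    p = min(spec.p_values)
    rows = []
    for f in factors:
        network = make_network(spec, weight_overrides={pathway: f})
        rng = np.random.default_rng(spec.child_seed("stim", f))
        pair = make_oddball(
            oddball_pair(df), p, spec.n_tones, spec.iai_ms, spec.duration_ms, rng
        )
        res = _simulate_pair(network, pair, tuning, spec, "cal", pathway, f)
        rows.append(
            {
                "pathway": pathway,
                "factor": f,
                "median_si": res.median_si,
                "signed_rank_p": res.signed_rank_p,
            }
        )
    return pd.DataFrame(rows)


def run_history_analysis(spec: ExperimentSpec) -> dict:
    """Oddball run reduced to the history-conditioned deviant response."""
    network = make_network(spec)
    tuning = make_tuning(spec)
    df = max(spec.delta_f)
    p = min(spec.p_values)
    rng = np.random.default_rng(spec.child_seed("stim"))
    seq, twin = make_oddball(
        oddball_pair(df), p, spec.n_tones, spec.iai_ms, spec.duration_ms, rng
    )
    rec = simulate(network, seq, tuning, seed=spec.child_seed("hist"))
    tab = count_spikes(rec, seq, spec.window_ms, n_units=spec.n_b)
    return {"table": tab, "curve": history_conditioned(tab)}


RUNNERS = {
    "oddball_grid": run_oddball_grid,
    "isi_sweep": run_isi_sweep,
    "duration_sweep": run_duration_sweep,
    "markov_sweep": run_markov_sweep,
    "grid_modes": run_grid_modes,
    "many_standards": run_many_standards,
    "calibration": run_calibration,
}
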