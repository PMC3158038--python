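"""Spike-train read-outs: per-tone counts, SSA indices, PSTHs, trend fits.

The central quantity is the SSA index (SI), a normalised contrast between
mean spike counts evoked by a frequency presented as deviant (d) versus as
standard (s):

    frequency-specific  SI(f)  = (d(f) - s(f)) / (d(f) + s(f))
    neuron-specific     SI     = (d1 + d2 - s1 - s2) / (d1 + d2 + s1 + s2)

Both lie in [-1, 1] and are undefined (flagged as NaN, excluded from
medians) when the denominator is zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .network import SpikeRecord
from .stimuli import DEVIANT, STANDARD, ToneSequence


def count_spikes(
    record: SpikeRecord,
    sequence: ToneSequence,
    window_ms: tuple[float, float] | None = None,
    population: str = "B",
    n_units: int | None = None,
) -> pd.DataFrame:
    """Per-(tone, unit) spike counts in a half-open analysis window.

    ``window_ms = (w0, w1)`` is relative to each tone onset; spikes in
    ``[onset + w0, onset + w1)`` are counted, so a spike exactly on the
    right edge belongs to the next window.  The default window is the full
    onset-to-onset epoch, which captures both phasic and tonic responses.
    Returns a tidy frame with one row per tone x unit, with the tone role
    and frequency joined.
    """
    iai = sequence.iai_ms
    if window_ms is None:
        window_ms = (0.0, iai)
    w0, w1 = window_ms
    if not 0.0 <= w0 < w1 <= iai:
        raise ValueError(
            "window must satisfy 0 <= w0 < w1 <= inter-onset interval "
            "(wider windows would overlap across tones)"
        )
    units, times = record.spikes[population]
    if n_units is None:
        n_units = int(units.max()) + 1 if units.size else 1
    onsets = np.array([e.onset_ms for e in sequence.events])
    n_tones = len(sequence)
    counts = np.zeros((n_tones, n_units), dtype=np.int64)
    if units.size:
        idx = np.searchsorted(onsets + w0, times, side="right") - 1
        ok = (idx >= 0) & (times < onsets[np.clip(idx, 0, None)] + w1) & (times >= onsets[np.clip(idx, 0, None)] + w0)
        np.add.at(counts, (idx[ok], units[ok]), 1)
    tone_index = np.repeat(np.arange(n_tones), n_units)
    return pd.DataFrame(
        {
            "tone_index": tone_index,
            "unit": np.tile(np.arange(n_units), n_tones),
            "count": counts.ravel(),
            "role": np.repeat([e.role for e in sequence.events], n_units),
            "freq_oct": np.repeat([e.freq_oct for e in sequence.events], n_units),
        }
    )


def si_frequency(d: float, s: float) -> float:
    """Frequency-specific SSA index (d - s)/(d + s); NaN if d + s == 0."""
    if d < 0 or s < 0:
        raise ValueError("mean counts must be >= 0")
    denom = d + s
    return np.nan if denom == 0 else (d - s) / denom


def si_neuron(d1: float, d2: float, s1: float, s2: float) -> float:
    """Neuron-specific SSA index pooling both frequencies; NaN on zero denominator."""
    for v in (d1, d2, s1, s2):
        if v < 0:
            raise ValueError("mean counts must be >= 0")
    denom = d1 + d2 + s1 + s2
    return np.nan if denom == 0 else (d1 + d2 - s1 - s2) / denom


@dataclass
class SIResult:
    """Per-unit SSA indices for an oddball pair plus population summaries."""

    per_unit: pd.DataFrame   # d1 s1 d2 s2 si_f1 si_f2 si_neuron, one row per unit
    median_si: float
    signed_rank_p: float
    n_units: int
    n_undefined: int

    def to_tsv(self, path, header: dict | None = None) -> None:
        with open(path, "w") as fh:
            for k, v in (header or {}).items():
                fh.write(f"# {k}={v}\n")
            fh.write(f"# median_si={self.median_si!r}\n")
            fh.write(f"# signed_rank_p={self.signed_rank_p!r}\n")
            self.per_unit.to_csv(fh, sep="\t", index=False)


def si_from_tables(table_1: pd.DataFrame, table_2: pd.DataFrame) -> SIResult:
    """SSA indices from the count tables of an oddball pair.

    ``table_1`` comes from the original sequence (frequency f1 standard,
    f2 deviant), ``table_2`` from the swapped twin (f1 deviant, f2
    standard), so every frequency is observed in both roles.
    """
    s1 = table_1[table_1.role == STANDARD].groupby("unit")["count"].mean()
    d2 = table_1[table_1.role == DEVIANT].groupby("unit")["count"].mean()
    d1 = table_2[table_2.role == DEVIANT].groupby("unit")["count"].mean()
    s2 = table_2[table_2.role == STANDARD].groupby("unit")["count"].mean()
    df = pd.DataFrame({"d1": d1, "s1": s1, "d2": d2, "s2": s2})
    df["si_f1"] = [si_frequency(r.d1, r.s1) for r in df.itertuples()]
    df["si_f2"] = [si_frequency(r.d2, r.s2) for r in df.itertuples()]
    df["si_neuron"] = [
        si_neuron(r.d1, r.d2, r.s1, r.s2) for r in df.itertuples()
    ]
    defined = df["si_neuron"].dropna()
    if len(defined) >= 5 and np.any(defined != 0):
        p = float(stats.wilcoxon(defined).pvalue)
    else:
        p = np.nan
    return SIResult(
        per_unit=df.reset_index(),
        median_si=float(defined.median()) if len(defined) else np.nan,
        signed_rank_p=p,
        n_units=len(df),
        n_undefined=int(df["si_neuron"].isna().sum()),
    )


def psth(
    record: SpikeRecord,
    sequence: ToneSequence,
    bin_ms: float = 2.0,
    population: str = "B",
    n_units: int | None = None,
    window_ms: float | None = None,
) -> pd.DataFrame:
    """Onset-aligned peri-stimulus time histograms in Hz.

    Averages over tones and units, separately for standards and deviants,
    and attaches the deviant-minus-standard difference waveform (the
    excess response to a deviant).  Bins are half-open on the right.
    """
    if bin_ms <= 0:
        raise ValueError("bin width must be > 0")
    if window_ms is None:
        window_ms = sequence.iai_ms
    units, times = record.spikes[population]
    if n_units is None:
        n_units = int(units.max()) + 1 if units.size else 1
    edges = np.arange(0.0, window_ms + bin_ms / 2, bin_ms)
    centres = edges[:-1] + bin_ms / 2.0
    out = {"time_ms": centres}
    role_counts = {}
    for role in (STANDARD, DEVIANT):
        onsets = np.array(
            [e.onset_ms for e in sequence.events if e.role == role]
        )
        role_counts[role] = len(onsets)
        if len(onsets) == 0:
            out[f"rate_{role}"] = np.zeros_like(centres)
            continue
        idx = np.searchsorted(onsets, times, side="right") - 1
        rel = times - onsets[np.clip(idx, 0, None)]
        ok = (idx >= 0) & (rel < window_ms)
        hist, _ = np.histogram(rel[ok], bins=edges)
        out[f"rate_{role}"] = hist / (len(onsets) * n_units * bin_ms / 1000.0)
    df = pd.DataFrame(out)
    df["rate_diff"] = df[f"rate_{DEVIANT}"] - df[f"rate_{STANDARD}"]
    return df


@dataclass
class HistoryCurve:
    """Normalised deviant response versus number of preceding standards."""

    table: pd.DataFrame       # k, mean_norm, sem, n  (k = 10 pools k >= 10)
    asymptote: float
    rate_per_tone: float      # 1/tau of the saturating exponential trend
    converged: bool


def history_conditioned(
    table: pd.DataFrame, k_pool: int = 10
) -> HistoryCurve:
    """Group deviant responses by the run length of preceding standards.

    The mean deviant count for each preceding-standard count ``k`` is
    normalised by the grand mean response over all tones; deviants with
    ``k >= k_pool`` are pooled into a single point.  A saturating
    exponential ``a * (1 - exp(-k/tau))`` is fitted by non-linear least
    squares.
    """
    roles = (
        table[["tone_index", "role"]]
        .drop_duplicates()
        .sort_values("tone_index")["role"]
        .tolist()
    )
    if DEVIANT not in roles:
        raise ValueError("table contains no deviants")
    grand_mean = table["count"].mean()
    per_tone = table.groupby("tone_index")["count"].mean()

    run = 0
    k_of_tone = {}
    for i, role in enumerate(roles):
        if role == DEVIANT:
            k_of_tone[i] = run
            run = 0
        else:
            run += 1
    rows = []
    ks = np.array(sorted(k_of_tone))
    kvals = np.array([min(k_of_tone[i], k_pool) for i in ks])
    resp = per_tone.loc[ks].to_numpy()
    for k in np.unique(kvals):
        sel = kvals == k
        vals = resp[sel] / grand_mean
        rows.append(
            {
                "k": int(k),
                "mean_norm": float(vals.mean()),
                "sem": float(vals.std(ddof=1) / np.sqrt(sel.sum())) if sel.sum() > 1 else np.nan,
                "n": int(sel.sum()),
            }
        )
    df = pd.DataFrame(rows)
    if len(df) < 3:  # too few distinct run lengths for a trend fit
        return HistoryCurve(df, float(df["mean_norm"].iloc[-1]), np.nan, False)
    fit = fit_exponential(df["k"].to_numpy(float), df["mean_norm"].to_numpy(), form="saturating")
    return HistoryCurve(df, fit.asymptote, fit.rate, fit.converged)


@dataclass
class FitResult:
    asymptote: float
    scale: float
    rate: float
    residual_norm: float
    converged: bool
    message: str = ""

    def __call__(self, x):
        x = np.asarray(x, dtype=float)
        return self.asymptote + self.scale * np.exp(-self.rate * x)


def fit_exponential(x, y, form: str = "decay") -> FitResult:
    """Least-squares exponential fit.

    ``decay``:      y = asymptote + scale * exp(-rate * x)   (scale > 0)
    ``saturating``: y = asymptote - scale * exp(-rate * x)   (rises to asymptote)

    Initial parameters come from a log-linear regression on the transformed
    data; non-convergence is reported in the result, never silently.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if form not in ("decay", "saturating"):
        raise ValueError("form must be 'decay' or 'saturating'")
    sign = 1.0 if form == "decay" else -1.0
    span = max(y.max() - y.min(), 1e-12)

    # log-linear start: log|y - c0| ~ log(scale) - rate * x
    c0 = y.min() - 0.05 * span if form == "decay" else y.max() + 0.05 * span
    resid0 = sign * (y - c0)
    resid0 = np.clip(resid0, 1e-12, None)
    slope, intercept = np.polyfit(x, np.log(resid0), 1)
    p0 = (c0, float(np.exp(intercept)), max(-slope, 1e-6))

    def model(xx, c, a, r):
        return c + sign * a * np.exp(-r * xx)

    try:
        popt, _ = optimize.curve_fit(
            model, x, y, p0=p0, maxfev=20_000,
            bounds=([-np.inf, 0.0, 0.0], [np.inf, np.inf, np.inf]),
        )
        resid = float(np.linalg.norm(model(x, *popt) - y))
        return FitResult(float(popt[0]), sign * float(popt[1]), float(popt[2]), resid, True)
    except RuntimeError as exc:  # no convergence
        resid = float(np.linalg.norm(model(x, *p0) - y))
        return FitResult(float(p0[0]), sign * float(p0[1]), float(p0[2]), resid, False, str(exc))


def signed_rank_test(values) -> float:
    """Two-sided Wilcoxon signed-rank p-value for median different from 0."""
    values = np.asarray(values, dtype=float)
    values = values[~np.isnan(values)]
    if values.size < 5:
        raise ValueError("signed-rank test needs at least 5 defined values")
    if np.all(values == 0):
        return 1.0
    return float(stats.wilcoxon(values).pvalue)


def ks_test(counts_a, counts_b) -> float:
    """Two-sample Kolmogorov-Smirnov p-value between count distributions."""
    a = np.asarray(counts_a, dtype=float)
    b = np.asarray(counts_b, dtype=float)
    if a.size < 5 or b.size < 5:
        raise ValueError("KS test needs at least 5 values per sample")
    return float(stats.ks_2samp(a, b).pvalue)


def sign_test_majority(deltas) -> tuple[int, int, float]:
    """Count of strictly positive vs negative values with a two-sided
    sign-test p-value (ties dropped); used for scatter-above-diagonal
    majorities."""
    deltas = np.asarray(deltas, dtype=float)
    deltas = deltas[~np.isnan(deltas)]
    n_above = int(np.sum(deltas > 0))
    n_below = int(np.sum(deltas < 0))
    n = n_above + n_below
    if n < 5:
        raise ValueError("sign test needs at least 5 non-tied values")
    p = float(stats.binomtest(n_above, n, 0.5).pvalue)
    return n_above, n_below, p
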