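"""Source-filter synthesis of sustained-[i] phonations and cohort simulation.

The generator exists so the whole pipeline is testable without clinical
recordings. A Rosenberg-type glottal flow pulse train (open quotient 0.6)
with per-cycle period and gain perturbations is differentiated, shaped by
a cascade of formant resonators (adult [i] targets by default), and mixed
with white noise at a gain that realizes a target harmonics-to-noise power
ratio.

Planted jitter and shimmer are expressed directly on the scale of the
corresponding local perturbation measures: the Gaussian per-cycle
perturbation SD is calibrated by sqrt(pi)/2 so that the *expected* local
jitter (mean |T_i - T_{i-1}| / mean T) equals ``jitter_pct``/100, and
likewise for shimmer.

Cohort simulation plants group-level acoustic shifts (high-risk: jitter
+0.0085, shimmer +0.0266, HNR -3.1 dB) and demographic structure
(high-risk older and more often male) with a demographically shifted
external site variant, so confound adjustment and external testing have
realistic structure to work against.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import signal as sps

from .audio_io import PhonationClip, highpass, normalize, write_clip
from .errors import VocalRiskError
from .features import PatientRecord

FS = 16_000

#: adult [i] formant targets (center Hz, bandwidth Hz) — standard values
DEFAULT_FORMANTS = [(270.0, 60.0), (2290.0, 100.0), (3010.0, 120.0)]

#: Gaussian SD multiplier so E[mean |dT|]/mean T equals the planted value
_HALF_NORMAL_CAL = float(np.sqrt(np.pi) / 2.0)


@dataclass
class VoiceParams:
    """Planted ground-truth parameters of one synthetic phonation."""

    f0: float = 140.0
    jitter_pct: float = 1.0
    shimmer_pct: float = 3.0
    target_hnr_db: float = 20.0
    formants: list = field(default_factory=lambda: list(DEFAULT_FORMANTS))
    duration_s: float = 1.0
    seed: int = 0
    f0_end: float | None = None     # linear F0 glide target, if any
    drift_pct: float = 0.5          # slow random F0 drift (SD, % of f0)
    open_quotient: float = 0.6

    def validate(self) -> None:
        if not (60.0 <= self.f0 <= 500.0):
            raise VocalRiskError(f"f0 {self.f0} outside [60, 500] Hz")
        if self.jitter_pct < 0 or self.shimmer_pct < 0:
            raise VocalRiskError("jitter_pct and shimmer_pct must be >= 0")
        if self.duration_s < 0.5:
            raise VocalRiskError("duration_s must be >= 0.5 s")


def _rosenberg_flow(phase: np.ndarray, period: float, oq: float) -> np.ndarray:
    """Rosenberg-C glottal flow over one cycle (phase in seconds from onset)."""
    tp = (2.0 / 3.0) * oq * period       # opening phase
    tn = oq * period - tp                # closing phase
    g = np.zeros_like(phase)
    rising = (phase >= 0) & (phase < tp)
    g[rising] = 0.5 * (1.0 - np.cos(np.pi * phase[rising] / tp))
    falling = (phase >= tp) & (phase < tp + tn)
    g[falling] = np.cos(0.5 * np.pi * (phase[falling] - tp) / tn)
    return g


def _resonator_cascade(x: np.ndarray, formants, fs: int) -> np.ndarray:
    for f, bw in formants:
        r = np.exp(-np.pi * bw / fs)
        theta = 2.0 * np.pi * f / fs
        b0 = 1.0 - 2.0 * r * np.cos(theta) + r * r
        x = sps.lfilter([b0], [1.0, -2.0 * r * np.cos(theta), r * r], x)
    return x


def synthesize_vowel(params: VoiceParams) -> PhonationClip:
    """Render one sustained-vowel clip at 16 kHz from planted parameters."""
    params.validate()
    rng = np.random.default_rng(params.seed)
    fs = FS
    n = int(round(params.duration_s * fs))

    sigma_j = _HALF_NORMAL_CAL * params.jitter_pct / 100.0
    sigma_s = _HALF_NORMAL_CAL * params.shimmer_pct / 100.0

    # cycle onsets with white timing jitter on a slowly drifting F0
    # contour; the pulse SHAPE follows the smooth contour only, so the
    # planted jitter is purely an onset-timing perturbation and stays on
    # the scale of the measured local jitter
    onsets, periods, shape_periods, gains = [], [], [], []
    t = 0.0
    drift = 0.0
    drift_sd = params.drift_pct / 100.0
    while t < params.duration_s:
        frac = t / params.duration_s
        f0_base = (params.f0 + (params.f0_end - params.f0) * frac
                   if params.f0_end is not None else params.f0)
        drift = 0.97 * drift + np.sqrt(1 - 0.97 ** 2) * rng.normal(0.0, drift_sd)
        f0_i = f0_base * (1.0 + drift)
        smooth_period = 1.0 / f0_i
        period = smooth_period * (1.0 + rng.normal(0.0, sigma_j))
        onsets.append(t)
        periods.append(period)
        shape_periods.append(smooth_period)
        gains.append(max(1.0 + rng.normal(0.0, sigma_s), 0.05))
        t += period

    flow = np.zeros(n + 4 * int(fs / params.f0))
    time = np.arange(len(flow)) / fs
    for t0, sp in zip(onsets, shape_periods):
        a = int(np.floor(t0 * fs))
        b = min(int(np.ceil((t0 + sp) * fs)) + 1, len(flow))
        flow[a:b] += _rosenberg_flow(time[a:b] - t0, sp,
                                     params.open_quotient)

    excitation = np.diff(flow, prepend=0.0)
    harmonic = _resonator_cascade(excitation, params.formants, fs)[:n]

    # per-cycle gains as amplitude modulation of the radiated waveform, so
    # the planted shimmer appears directly in per-cycle waveform peaks
    # (applying gains at the source would be diluted by formant ringing
    # carrying over between cycles); transitions smoothed over ~1 ms
    env = np.ones(n)
    for t0, period, gain in zip(onsets, periods, gains):
        a = int(np.floor(t0 * fs))
        b = min(int(np.ceil((t0 + period) * fs)) + 1, n)
        if a >= n:
            break
        env[a:b] = gain
    kernel = np.hanning(17)
    env = np.convolve(env, kernel / kernel.sum(), mode="same")
    harmonic = harmonic * env

    p_h = float(np.mean(harmonic ** 2))
    if p_h <= 0:
        raise VocalRiskError("zero harmonic energy; cannot realize target HNR")
    p_n = p_h / (10.0 ** (params.target_hnr_db / 10.0))
    x = harmonic + rng.normal(0.0, np.sqrt(p_n), n)
    x *= 0.5 / np.max(np.abs(x))
    return PhonationClip(samples=x, sample_rate=fs)


def standardize_clip(clip: PhonationClip, norm_mode: str = "peak") -> PhonationClip:
    """Apply the in-memory equivalent of the audio standardization chain
    (already at 16 kHz: high-pass then amplitude normalization)."""
    x = normalize(highpass(clip.samples), norm_mode)
    return PhonationClip(samples=x, clip_id=clip.clip_id,
                         patient_id=clip.patient_id, sample_rate=clip.sample_rate)


# ---------------------------------------------------------------------------
# cohort simulation


@dataclass
class GroupSpec:
    """Distributions for one risk group."""

    n: int
    jitter_mean: float
    shimmer_mean: float
    hnr_mean_db: float
    age_mean: float
    age_sd: float
    p_male: float
    jitter_sd: float = 0.006
    shimmer_sd: float = 0.02
    hnr_sd_db: float = 3.0


@dataclass
class CohortSpec:
    """Two-site synthetic study design.

    Defaults plant the published group contrasts: high-risk phonations
    have jitter higher by 0.0085, shimmer by 0.0266 and HNR lower by
    3.1 dB than low-risk; the high-risk group is older (mean 72.3 vs 62.9
    years) and more often male (83% vs 45.5%). The moderate group sits at
    the midpoint of the high/low parameter means.
    """

    high: GroupSpec = field(default_factory=lambda: GroupSpec(
        n=47, jitter_mean=0.0175, shimmer_mean=0.0566, hnr_mean_db=14.9,
        age_mean=72.3, age_sd=9.9, p_male=0.83))
    low: GroupSpec = field(default_factory=lambda: GroupSpec(
        n=99, jitter_mean=0.009, shimmer_mean=0.030, hnr_mean_db=18.0,
        age_mean=62.9, age_sd=12.6, p_male=0.455))
    n_moderate: int = 17
    clips_min: int = 1
    clips_max: int = 3
    #: weights over {clips_min..clips_max}; the default favors 3 clips,
    #: matching cohorts that averaged about three usable phonations
    clips_weights: tuple = (0.1, 0.2, 0.7)
    duration_s: float = 1.0
    site: str = "development"
    seed: int = 0
    #: weak demographic links to voice, for the confound machinery to absorb
    f0_female: float = 205.0
    f0_male: float = 125.0
    f0_sd: float = 18.0
    jitter_per_year: float = 5e-5   # extra jitter per year above age 60

    def null_effects(self) -> "CohortSpec":
        """Copy with every group contrast removed — acoustic and
        demographic — so the label carries no information at all (the
        model receives age and sex as covariates, so a demographic
        contrast alone would still discriminate)."""
        mid = self._midpoint()
        age_mean = (self.high.age_mean + self.low.age_mean) / 2
        age_sd = (self.high.age_sd + self.low.age_sd) / 2
        p_male = (self.high.p_male + self.low.p_male) / 2
        common = dict(jitter_mean=mid[0], shimmer_mean=mid[1],
                      hnr_mean_db=mid[2], age_mean=age_mean, age_sd=age_sd,
                      p_male=p_male)
        return replace(self, high=replace(self.high, **common),
                       low=replace(self.low, **common))

    def _midpoint(self):
        return ((self.high.jitter_mean + self.low.jitter_mean) / 2,
                (self.high.shimmer_mean + self.low.shimmer_mean) / 2,
                (self.high.hnr_mean_db + self.low.hnr_mean_db) / 2)


def external_site_spec(base: CohortSpec | None = None, seed: int = 1) -> CohortSpec:
    """External-cohort variant: smaller (19 high / 16 low), older, with a
    higher share of female high-risk and fewer male low-risk patients."""
    base = base if base is not None else CohortSpec()
    high = replace(base.high, n=19, p_male=12 / 19, age_mean=74.0, age_sd=13.4)
    low = replace(base.low, n=16, p_male=3 / 16, age_mean=67.0, age_sd=13.4)
    return replace(base, high=high, low=low, n_moderate=0,
                   site="external", seed=seed)


def _draw_patient(rng: np.random.Generator, group: GroupSpec, label: str,
                  spec: CohortSpec, pid: str) -> tuple[PatientRecord, dict]:
    age = float(np.clip(rng.normal(group.age_mean, group.age_sd), 25.0, 95.0))
    sex = "male" if rng.random() < group.p_male else "female"
    f0_base = rng.normal(spec.f0_male if sex == "male" else spec.f0_female,
                         spec.f0_sd)
    f0_base = float(np.clip(f0_base, 80.0, 320.0))
    jitter = rng.normal(group.jitter_mean, group.jitter_sd)
    jitter += spec.jitter_per_year * max(age - 60.0, 0.0)
    jitter = float(np.clip(jitter, 0.001, 0.08))
    shimmer = float(np.clip(rng.normal(group.shimmer_mean, group.shimmer_sd),
                            0.005, 0.25))
    hnr = float(np.clip(rng.normal(group.hnr_mean_db, group.hnr_sd_db), 2.0, 35.0))

    counts = np.arange(spec.clips_min, spec.clips_max + 1)
    w = np.asarray(spec.clips_weights, dtype=np.float64)
    n_clips = int(rng.choice(counts, p=w / w.sum()))
    clips = []
    for c in range(n_clips):
        params = VoiceParams(
            f0=float(np.clip(f0_base * (1.0 + rng.normal(0.0, 0.02)), 80.0, 340.0)),
            jitter_pct=jitter * 100.0, shimmer_pct=shimmer * 100.0,
            target_hnr_db=hnr, duration_s=spec.duration_s,
            seed=int(rng.integers(0, 2 ** 31)))
        clip = synthesize_vowel(params)
        clip.clip_id = f"{pid}_c{c}"
        clip.patient_id = pid
        clips.append(clip)
    record = PatientRecord(patient_id=pid, age=age, sex=sex, risk_label=label,
                           clips=clips, site=spec.site)
    truth = {"patient_id": pid, "risk_label": label, "age": age, "sex": sex,
             "f0_base": f0_base, "jitter": jitter, "shimmer": shimmer,
             "hnr_db": hnr, "n_clips": n_clips}
    return record, truth


def simulate_cohort(spec: CohortSpec, out_dir: str | Path | None = None
                    ) -> tuple[list[PatientRecord], list[dict]]:
    """Draw a full synthetic cohort.

    Returns the patient records (clips in memory) and a ground-truth table
    of every planted parameter. When ``out_dir`` is given, 16-bit PCM WAVs,
    a manifest CSV and the ground-truth CSV are written there.
    """
    for group, name in ((spec.high, "high"), (spec.low, "low")):
        if group.n <= 0:
            raise VocalRiskError(f"group '{name}' must have positive size")
    if spec.n_moderate < 0:
        raise VocalRiskError("n_moderate must be >= 0")

    rng = np.random.default_rng(spec.seed)
    mid_j, mid_s, mid_h = spec._midpoint()
    mid_age = (spec.high.age_mean + spec.low.age_mean) / 2
    mid_sd = (spec.high.age_sd + spec.low.age_sd) / 2
    mid_male = (spec.high.p_male + spec.low.p_male) / 2
    moderate = GroupSpec(n=spec.n_moderate, jitter_mean=mid_j, shimmer_mean=mid_s,
                         hnr_mean_db=mid_h, age_mean=mid_age, age_sd=mid_sd,
                         p_male=mid_male, jitter_sd=spec.high.jitter_sd,
                         shimmer_sd=spec.high.shimmer_sd,
                         hnr_sd_db=spec.high.hnr_sd_db)

    patients, truths = [], []
    counter = 0
    for group, label in ((spec.high, "high"), (spec.low, "low"),
                         (moderate, "moderate")):
        for _ in range(group.n):
            pid = f"{spec.site[:3]}{counter:04d}"
            counter += 1
            record, truth = _draw_patient(rng, group, label, spec, pid)
            patients.append(record)
            truths.append(truth)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        manifest_rows = []
        for p in patients:
            for clip in p.clips:
                wav = out / f"{clip.clip_id}.wav"
                write_clip(clip, wav)
                manifest_rows.append({"patient_id": p.patient_id,
                                      "clip_id": clip.clip_id,
                                      "path": wav.name, "age": p.age,
                                      "sex": p.sex, "risk_label": p.risk_label,
                                      "site": p.site})
        for name, rows in (("manifest.csv", manifest_rows),
                           ("ground_truth.csv", truths)):
            with open(out / name, "w", newline="") as fh:
                writer = csv.DictWriter(fh, fieldnames=list(rows[0]))
                writer.writeheader()
                writer.writerows(rows)
    return patients, truths
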