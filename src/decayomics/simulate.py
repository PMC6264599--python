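"""Synthetic rifampicin-chase experiment generator.

Emulates the experimental design of a genome-wide mRNA stability study in
stationary-phase *E. coli*: three strains (an rph-1 control and two
exoribonuclease deletion mutants), each measured on twelve microarrays --
three biological replicates sampled at t = 0 plus nine post-rifampicin time
points on three replicate-specific schedules (0/2/8/15, 0/5/10/18 and
0/3/12/30 minutes).  Each transcript is probed by a fixed number of probes
(default 16) with transcript-specific probe affinities.

Every generated dataset carries a full ground truth (degradation rate
constant k, transcription-arrest delay tau, steady-state concentration,
differential-expression effect and saturation-phase regime per transcript),
so the downstream estimation pipeline can be validated by parameter
recovery rather than by eyeballing.

The decay law is first-order with an optional arrest delay: the
concentration stays at its baseline C0 for t <= tau and follows
C0 * exp(-k (t - tau)) afterwards.  Probe intensity is
affinity * C(t) * exp(eps) + background, with eps ~ N(0, noise_sd_ln) and an
additive Gaussian array background floored at a small positive constant.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

LN2 = float(np.log(2.0))

#: Saturation regimes of the degradation machinery, ordered by increasing
#: steady-state concentration.
PHASE_REGIMES = ("substrate_limited", "intermediate", "saturated")

DEFAULT_SCHEDULES = (
    (0.0, 2.0, 8.0, 15.0),
    (0.0, 5.0, 10.0, 18.0),
    (0.0, 3.0, 12.0, 30.0),
)

DEFAULT_YIELDS = {"control": 15.6, "d_rnr": 17.2, "d_pnp": 35.9}


class ValidationError(ValueError):
    """Raised when a configuration or input table violates its contract."""


@dataclass
class SimConfig:
    """Design parameters of the simulated experiment.

    Defaults mirror the emulated study: 16 probes per transcript, three
    strains on the three four-point schedules, RNA extraction yields of
    15.6 / 17.2 / 35.9 ug RNA per mg dry cell weight, half-lives log-normal
    around a 24-minute median, and a three-regime concentration structure
    (substrate-limited / intermediate / saturated) with planted
    within-regime correlations between ln k and ln C.
    """

    n_transcripts: int = 2000
    probes_per_transcript: int = 16
    strains: tuple[str, ...] = ("control", "d_rnr", "d_pnp")
    schedules: tuple[tuple[float, ...], ...] = DEFAULT_SCHEDULES
    noise_sd_ln: float = 0.2
    #: ln-sd of biological replicate variability: each replicate culture's
    #: baseline concentration deviates by this much per transcript, shared
    #: across that replicate's four time points
    bio_sd_ln: float = 0.05
    background_mean: float = 50.0
    background_sd: float = 10.0
    #: ln-sd of the fixed per-probe background multiplier (sequence-specific
    #: background level; gives background probes a stable rank order)
    background_probe_sd_ln: float = 0.3
    #: fraction of transcripts effectively silent in late stationary phase;
    #: their probes sit in the array background
    unexpressed_fraction: float = 0.35
    #: (mean, sd) of ln concentration for unexpressed transcripts (AU)
    unexpressed_ln_conc: tuple[float, float] = (1.0, 0.5)
    yields: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_YIELDS))
    t_half_median: float = 24.0
    t_half_gsd: float = 1.8
    #: half-life range resolvable by the 0-30 min chase design (minutes);
    #: the lognormal is truncated to this interval
    t_half_min: float = 4.0
    t_half_max: float = 60.0
    #: transcription-arrest delay tau in minutes; scalar or mapping per strain
    delay_minutes: float | dict[str, float] = 0.0
    affinity_sd_ln: float = 0.15
    phase_fractions: tuple[float, float, float] = (0.60, 0.25, 0.15)
    #: planted Pearson correlation between ln k and ln C within each regime
    phase_r: tuple[float, float, float] = (-0.80, -0.65, 0.0)
    #: natural-log concentration centers of the three regimes (AU); spaced
    #: 6 within-regime sd apart so the regimes are separable concentration zones
    phase_ln_conc_centers: tuple[float, float, float] = (7.5, 10.5, 13.5)
    phase_ln_conc_sd: float = 0.5
    #: per-strain fraction of transcripts differentially expressed vs control
    de_fraction: dict[str, float] = field(default_factory=lambda: {"d_pnp": 0.10})
    #: magnitude of the planted differential-expression effect (log2)
    de_log2fc: float = 2.0
    #: per-strain fraction of transcripts with accelerated decay
    destabilized_fraction: dict[str, float] = field(
        default_factory=lambda: {"d_pnp": 0.20}
    )
    #: multiplicative change of k for destabilized transcripts (>1 = faster decay)
    destabilized_k_fold: float = 2.0
    #: per-strain genome-wide multiplicative shift of k (a small global
    #: stabilization, below per-gene detectability, as seen without RNase R)
    global_k_fold: dict[str, float] = field(
        default_factory=lambda: {"d_rnr": 24.2 / 28.3}
    )
    intensity_floor: float = 1e-6
    seed: int = 0

    def delay_for(self, strain: str) -> float:
        if isinstance(self.delay_minutes, dict):
            return float(self.delay_minutes.get(strain, 0.0))
        return float(self.delay_minutes)

    def validate(self) -> "SimConfig":
        if self.n_transcripts < 1:
            raise ValidationError("n_transcripts must be >= 1")
        if self.probes_per_transcript < 1:
            raise ValidationError("probes_per_transcript must be >= 1")
        if len(self.strains) < 1:
            raise ValidationError("strains must be non-empty")
        if len(set(self.strains)) != len(self.strains):
            raise ValidationError("strains must be unique")
        for sched in self.schedules:
            t = np.asarray(sched, dtype=float)
            if t.size < 2:
                raise ValidationError("schedules: each schedule needs >= 2 points")
            if t[0] != 0.0:
                raise ValidationError("schedules: every schedule must start at 0")
            if np.any(np.diff(t) <= 0):
                raise ValidationError("schedules: times must be strictly increasing")
            if np.any(t < 0):
                raise ValidationError("schedules: times must be non-negative")
        if self.noise_sd_ln < 0:
            raise ValidationError("noise_sd_ln must be >= 0")
        if self.bio_sd_ln < 0:
            raise ValidationError("bio_sd_ln must be >= 0")
        if self.background_sd < 0:
            raise ValidationError("background_sd must be >= 0")
        if self.background_probe_sd_ln < 0:
            raise ValidationError("background_probe_sd_ln must be >= 0")
        if not 0.0 <= self.unexpressed_fraction < 1.0:
            raise ValidationError("unexpressed_fraction must lie in [0, 1)")
        for s in self.strains:
            if s not in self.yields:
                raise ValidationError(f"yields: missing strain {s!r}")
            if self.yields[s] <= 0:
                raise ValidationError(f"yields: yield for {s!r} must be > 0")
        if self.t_half_median <= 0:
            raise ValidationError("t_half_median must be > 0")
        if self.t_half_gsd < 1.0:
            raise ValidationError("t_half_gsd must be >= 1")
        if not 0 < self.t_half_min < self.t_half_median < self.t_half_max:
            raise ValidationError(
                "t_half_min < t_half_median < t_half_max must hold with all > 0"
            )
        fr = np.asarray(self.phase_fractions, dtype=float)
        if fr.size != 3 or np.any(fr < 0) or not np.isclose(fr.sum(), 1.0):
            raise ValidationError("phase_fractions must be 3 non-negative values summing to 1")
        if self.phase_ln_conc_sd <= 0:
            raise ValidationError("phase_ln_conc_sd must be > 0")
        for r in self.phase_r:
            if not -1.0 < r < 1.0:
                raise ValidationError("phase_r values must lie in (-1, 1)")
        for s, f in self.de_fraction.items():
            if not 0.0 <= f <= 1.0:
                raise ValidationError(f"de_fraction[{s!r}] must lie in [0, 1]")
        for s, f in self.destabilized_fraction.items():
            if not 0.0 <= f <= 1.0:
                raise ValidationError(f"destabilized_fraction[{s!r}] must lie in [0, 1]")
        if self.destabilized_k_fold <= 0:
            raise ValidationError("destabilized_k_fold must be > 0")
        if any(f <= 0 for f in self.global_k_fold.values()):
            raise ValidationError("global_k_fold values must be > 0")
        delays = (
            self.delay_minutes.values()
            if isinstance(self.delay_minutes, dict)
            else [self.delay_minutes]
        )
        if any(d < 0 for d in delays):
            raise ValidationError("delay_minutes must be >= 0")
        return self

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class TruthTable:
    """Ground truth of a simulated cohort.

    ``transcripts`` holds one row per transcript with its saturation regime
    and, per strain, columns ``k_<strain>`` (min^-1), ``delay_<strain>``
    (min), ``conc_<strain>`` (steady-state abundance, AU) and
    ``de_log2fc_<strain>``.  ``affinities`` holds one row per probe with its
    positive affinity multiplier.
    """

    transcripts: pd.DataFrame
    affinities: pd.DataFrame
    strains: tuple[str, ...]

    def k(self, strain: str) -> pd.Series:
        return self.transcripts.set_index("transcript_id")[f"k_{strain}"]

    def t_half(self, strain: str) -> pd.Series:
        return LN2 / self.k(strain)

    def conc(self, strain: str) -> pd.Series:
        return self.transcripts.set_index("transcript_id")[f"conc_{strain}"]


def generate_truth(config: SimConfig) -> TruthTable:
    """Draw a ground-truth cohort under the configured study conditions.

    Half-lives are log-normal (median ``t_half_median``, geometric sd
    ``t_half_gsd``).  Concentrations follow the three-regime model: in the
    substrate-limited and intermediate regimes ln C = a - b ln k + eps with
    b and sd(eps) derived from the planted within-regime correlation; in the
    saturated regime ln C is drawn from the top concentration range
    independently of k.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 0])
    n = config.n_transcripts
    ids = np.array([f"t{i:05d}" for i in range(n)])

    regime_idx = rng.choice(3, size=n, p=np.asarray(config.phase_fractions, float))
    t_half = _truncated_lognormal_thalf(rng, config, n)
    k_base = LN2 / t_half
    lnk = np.log(k_base)
    mean_lnk = float(lnk.mean())
    sd_lnk = float(lnk.std())

    s = config.phase_ln_conc_sd
    ln_conc = np.empty(n)
    for j in range(3):
        mask = regime_idx == j
        m = int(mask.sum())
        if m == 0:
            continue
        center = config.phase_ln_conc_centers[j]
        r = config.phase_r[j]
        if j == 2 or sd_lnk == 0.0:
            # saturated regime: concentration independent of k
            ln_conc[mask] = center + s * rng.normal(size=m)
        else:
            b = -r * s / sd_lnk
            eps_sd = s * np.sqrt(1.0 - r * r)
            ln_conc[mask] = (
                center - b * (lnk[mask] - mean_lnk) + eps_sd * rng.normal(size=m)
            )
    expressed = rng.random(n) >= config.unexpressed_fraction
    if not expressed.all():
        m = int((~expressed).sum())
        mu_u, sd_u = config.unexpressed_ln_conc
        ln_conc[~expressed] = rng.normal(mu_u, sd_u, size=m)
    conc_base = np.exp(ln_conc)

    cols: dict[str, np.ndarray] = {
        "transcript_id": ids,
        "phase_regime": np.array(PHASE_REGIMES, dtype=object)[regime_idx],
        "expressed": expressed,
    }
    control = config.strains[0]
    for strain in config.strains:
        k_strain = k_base * config.global_k_fold.get(strain, 1.0)
        de = np.zeros(n)
        if strain != control:
            frac = config.destabilized_fraction.get(strain, 0.0)
            if frac > 0:
                hit = rng.random(n) < frac
                k_strain[hit] *= config.destabilized_k_fold
            de_frac = config.de_fraction.get(strain, 0.0)
            if de_frac > 0:
                hit = rng.random(n) < de_frac
                sign = np.where(rng.random(n) < 0.5, -1.0, 1.0)
                de[hit] = sign[hit] * config.de_log2fc
        cols[f"k_{strain}"] = k_strain
        cols[f"delay_{strain}"] = np.full(n, config.delay_for(strain))
        cols[f"conc_{strain}"] = conc_base * np.exp2(de)
        cols[f"de_log2fc_{strain}"] = de

    transcripts = pd.DataFrame(cols)

    p = config.probes_per_transcript
    probe_ids = np.array([f"{tid}_p{j:02d}" for tid in ids for j in range(p)])
    affinities = pd.DataFrame(
        {
            "probe_id": probe_ids,
            "transcript_id": np.repeat(ids, p),
            "affinity": np.exp(rng.normal(0.0, config.affinity_sd_ln, size=n * p)),
            # sequence-specific background level, fixed across arrays
            "background_factor": np.exp(
                rng.normal(0.0, config.background_probe_sd_ln, size=n * p)
            ),
        }
    )
    truth = TruthTable(transcripts, affinities, tuple(config.strains))
    _check_truth(truth, config)
    return truth


def _truncated_lognormal_thalf(
    rng: np.random.Generator, config: SimConfig, n: int
) -> np.ndarray:
    """Half-lives from a lognormal truncated to the resolvable range.

    The parent location is calibrated so the *truncated* distribution has
    median ``t_half_median``.
    """
    from scipy import stats as _st
    from scipy.optimize import brentq

    sd = float(np.log(config.t_half_gsd))
    lo, hi, med = config.t_half_min, config.t_half_max, config.t_half_median
    if sd == 0.0:
        return np.full(n, med)

    def trunc_median(log_m0: float) -> float:
        f = _st.norm(loc=log_m0, scale=sd)
        q = 0.5 * (f.cdf(np.log(lo)) + f.cdf(np.log(hi)))
        return float(f.ppf(q))

    log_med = float(
        brentq(lambda m: trunc_median(m) - np.log(med), np.log(lo), np.log(hi))
    )
    f = _st.norm(loc=log_med, scale=sd)
    u = rng.uniform(f.cdf(np.log(lo)), f.cdf(np.log(hi)), size=n)
    return np.exp(f.ppf(u))


def _check_truth(truth: TruthTable, config: SimConfig) -> None:
    for strain in truth.strains:
        k = truth.transcripts[f"k_{strain}"].to_numpy()
        if not np.all(np.isfinite(k)) or np.any(k <= 0):
            raise ValidationError(f"k_{strain}: rates must be finite and > 0")
    aff = truth.affinities["affinity"].to_numpy()
    if np.any(aff <= 0):
        raise ValidationError("affinity: multipliers must be > 0")
    per = truth.affinities.groupby("transcript_id").size()
    if not (per == config.probes_per_transcript).all():
        raise ValidationError("affinity: wrong probe count for some transcript")


def concentration_at(
    conc0: np.ndarray, k: np.ndarray, delay: float, t: float
) -> np.ndarray:
    """First-order decay with a flat baseline during the arrest delay."""
    if t <= delay:
        return np.asarray(conc0, dtype=float).copy()
    return conc0 * np.exp(-k * (t - delay))


def generate_arrays(truth: TruthTable, config: SimConfig):
    """Simulate probe-level intensities for the full array design.

    Returns ``(probes, sheet)`` where ``probes`` is a
    :class:`~decayomics.io.ProbeMatrix` (probes x arrays) and ``sheet`` the
    sample sheet with columns array_id, strain, replicate, time_min, role.
    The three t = 0 arrays per strain are the T0 replicates and double as
    the steady-state samples (role ``T0``).
    """
    from .io import ProbeMatrix  # local import to avoid a cycle

    config.validate()
    for strain in config.strains:
        if f"k_{strain}" not in truth.transcripts.columns:
            raise ValidationError(f"truth does not cover strain {strain!r}")
    rng = np.random.default_rng([config.seed, 1])

    tt = truth.transcripts
    ids = tt["transcript_id"].to_numpy()
    n = len(ids)
    tix = {tid: i for i, tid in enumerate(ids)}
    probe_t = truth.affinities["transcript_id"].map(tix).to_numpy()
    aff = truth.affinities["affinity"].to_numpy()
    if "background_factor" in truth.affinities.columns:
        bg_factor = truth.affinities["background_factor"].to_numpy()
    else:
        bg_factor = np.ones_like(aff)

    sheet_rows = []
    columns: dict[str, np.ndarray] = {}
    for strain in config.strains:
        conc0 = tt[f"conc_{strain}"].to_numpy(dtype=float)
        k = tt[f"k_{strain}"].to_numpy(dtype=float)
        tau = config.delay_for(strain)
        for rep, sched in enumerate(config.schedules, start=1):
            # each replicate is an independent culture: its baseline level
            # deviates per transcript, identically at all its time points
            if config.bio_sd_ln > 0:
                rep_conc = conc0 * np.exp(
                    rng.normal(0.0, config.bio_sd_ln, size=n)
                )
            else:
                rep_conc = conc0
            for t in sched:
                array_id = f"{strain}_r{rep}_t{t:g}"
                ct = concentration_at(rep_conc, k, tau, float(t))
                signal = aff * ct[probe_t]
                if config.noise_sd_ln > 0:
                    signal = signal * np.exp(
                        rng.normal(0.0, config.noise_sd_ln, size=signal.shape)
                    )
                if config.background_mean != 0.0 or config.background_sd > 0.0:
                    bg = rng.normal(
                        config.background_mean * bg_factor,
                        config.background_sd,
                        size=signal.shape,
                    )
                    signal = signal + bg
                columns[array_id] = np.maximum(signal, config.intensity_floor)
                sheet_rows.append(
                    {
                        "array_id": array_id,
                        "strain": strain,
                        "replicate": rep,
                        "time_min": float(t),
                        "role": "T0" if t == 0 else "decay",
                    }
                )

    values = pd.DataFrame(columns, index=truth.affinities["probe_id"].to_numpy())
    values.index.name = "probe_id"
    transcripts = pd.Series(
        truth.affinities["transcript_id"].to_numpy(),
        index=values.index,
        name="transcript_id",
    )
    probes = ProbeMatrix(transcripts, values)
    probes.validate(config.probes_per_transcript)
    sheet = pd.DataFrame(sheet_rows)

    n_expected = len(config.schedules) * len(config.schedules[0])
    per_strain = sheet.groupby("strain").size()
    if not (per_strain == n_expected).all():
        raise ValidationError("array design does not match schedule/replicate counts")
    return probes, sheet


def generate_counts(
    n_features: int,
    libsizes_a,
    libsizes_b,
    log2fc,
    dispersion: float,
    seed: int,
    base_mean: float = 500.0,
) -> pd.DataFrame:
    """Simulate an ncRNA count table for two conditions.

    Counts are gamma-Poisson (negative binomial) with per-feature base
    abundance, per-sample library-size factors, and a planted log2 fold
    change applied to condition B, so the expected library-size-normalized
    B/A ratio equals ``2**log2fc``.  ``dispersion`` is the NB dispersion
    (variance = mu + dispersion * mu^2); 0 gives the Poisson limit.
    """
    libsizes_a = np.asarray(libsizes_a, dtype=float)
    libsizes_b = np.asarray(libsizes_b, dtype=float)
    if n_features < 1:
        raise ValidationError("n_features must be >= 1")
    if np.any(libsizes_a <= 0) or np.any(libsizes_b <= 0):
        raise ValidationError("libsizes must be > 0")
    if dispersion < 0:
        raise ValidationError("dispersion must be >= 0")
    log2fc = np.broadcast_to(np.asarray(log2fc, dtype=float), (n_features,)).copy()
    if base_mean <= 0:
        raise ValidationError("base_mean must be > 0")

    rng = np.random.default_rng(seed)
    base = base_mean * np.exp(rng.normal(0.0, 0.5, size=n_features))
    samples = {}
    for j, ls in enumerate(libsizes_a, start=1):
        mu = base * ls
        samples[f"A_{j}"] = _nb_draw(rng, mu, dispersion)
    for j, ls in enumerate(libsizes_b, start=1):
        mu = base * ls * np.exp2(log2fc)
        samples[f"B_{j}"] = _nb_draw(rng, mu, dispersion)
    idx = pd.Index([f"nc{i:04d}" for i in range(n_features)], name="feature_id")
    return pd.DataFrame(samples, index=idx)


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    if dispersion == 0.0:
        return rng.poisson(mu)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mu * dispersion)
    return rng.poisson(lam)
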