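"""Simulated crossover listening study and its statistical pipeline.

Fifteen synthetic cochlear-implant listeners are modelled as psychometric
functions on the STOI axis: the probability of recognising a word is a
logistic function of the objective intelligibility of the presented
stimulus.  Each simulated session mirrors the clinical protocol: the RT60
at which the listener scores 50 % words correct (RT60_50%) is titrated
first, then six conditions (clean / reverberated, each unprocessed or
processed with WPE or WPEPF) are tested and retested at that personal
operating point, followed by paired subjective ratings.

The analysis pipeline applies the rationalised arcsine transform to the
percent-correct scores, fits linear mixed models with a subject random
intercept (REML, i.i.d. residuals - the "scaled identity" covariance),
runs Sidak-corrected pairwise comparisons, one-sample t tests against
indifference for the ratings, and ICC(3,1) for test-retest reliability.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.signal
import scipy.special
import scipy.stats
import statsmodels.formula.api as smf

from .dereverb import PostFilterConfig, WpeConfig, late_reverb_postfilter, \
    oracle_psd, wpe_dereverb
from .room import simulate_rir, study_room
from .spectral import StftConfig, analyze, synthesize
from .stimuli import CONDITIONS, generate_pseudo_sentence
from .stoi import compute_stoi

#: population mean of the listeners' 50%-point on the STOI axis.  This is
#: the calibration anchor of the simulated cohort: it equals the mean STOI
#: of the synthetic sentences reverberated at RT60 = 1.0 s (recomputed by
#: scripts/calibrate_listeners.py), so the cohort's median RT60_50% lands
#: at ~1.0 s by construction.
S50_POPULATION_MEAN = 0.547
S50_POPULATION_SD = 0.04
#: s50 is truncated to the STOI range the titration grid can actually
#: reach (mean STOI ~0.74 at RT60 0.4 s down to ~0.49 at 1.4 s), so every
#: listener's psychometric function crosses 50% within the grid
S50_TRUNCATION = (0.51, 0.635)
SLOPE_RANGE = (12.0, 20.0)
LAPSE_MAX = 0.05

WORDS_PER_SENTENCE = 5
TITRATION_GRID = np.round(np.arange(0.4, 1.4001, 0.1), 2)
#: reverberant stimuli exist on a 0.05 s RT60 grid (0.4-1.5 s); personal
#: operating points are rounded to it
STIMULUS_RT60_STEP = 0.05

#: subjective-rating pairs, (expected-preferred, other); the first four are
#: the measurement pairs, the last four controls
RATING_PAIRS = (
    ("clean", "reverb"),
    ("reverb_wpe", "reverb"),
    ("reverb_wpepf", "reverb"),
    ("reverb_wpepf", "reverb_wpe"),
    ("clean", "clean_wpe"),
    ("clean", "clean_wpepf"),
    ("clean_wpe", "clean_wpepf"),
    ("reverb", "reverb"),
)
RATING_OUTCOMES = ("effort", "naturalness", "intelligibility")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ListenerProfile:
    subject_id: str
    s50: float
    slope: float
    lapse: float
    rng_seed: int

    def __post_init__(self):
        if not 0.0 < self.s50 < 1.0:
            raise ValueError("s50 must be in (0, 1)")
        if self.slope <= 0:
            raise ValueError("slope must be positive")
        if not 0.0 <= self.lapse <= 0.1:
            raise ValueError("lapse must be in [0, 0.1]")

    def p_correct(self, stoi: float) -> float:
        return (1.0 - self.lapse) * float(
            scipy.special.expit(self.slope * (stoi - self.s50)))


@dataclass(frozen=True)
class ThresholdResult:
    rt60_50: float
    grid: np.ndarray
    percents: np.ndarray


@dataclass(frozen=True)
class LmmResult:
    fixed_effects: pd.DataFrame       # estimate, se per fixed-effect term
    random_intercept_var: float
    residual_var: float
    omnibus: pd.DataFrame             # effect, F, p per tested term
    pairwise: pd.DataFrame | None     # estimate, se, t, p, p_sidak


@dataclass(frozen=True)
class IccResult:
    icc3: float
    ci95: tuple[float, float]


# ---------------------------------------------------------------------------
# listener population
# ---------------------------------------------------------------------------

def default_listeners(n: int = 15, seed: int = 0) -> list[ListenerProfile]:
    """Synthetic cohort calibrated so median RT60_50% is ~1.0 s."""
    rng = np.random.default_rng(seed)
    lo, hi = S50_TRUNCATION
    # place the location parameter so the *truncated* median equals the
    # calibration anchor (the asymmetric truncation would otherwise pull
    # the cohort's median s50, hence its median RT60_50%, off target)
    loc = scipy.optimize.brentq(
        lambda m: scipy.stats.truncnorm.median(
            (lo - m) / S50_POPULATION_SD, (hi - m) / S50_POPULATION_SD,
            loc=m, scale=S50_POPULATION_SD) - S50_POPULATION_MEAN,
        S50_POPULATION_MEAN - 3 * S50_POPULATION_SD,
        S50_POPULATION_MEAN + S50_POPULATION_SD)
    a, b = (lo - loc) / S50_POPULATION_SD, (hi - loc) / S50_POPULATION_SD
    listeners = []
    for i in range(n):
        s50 = float(scipy.stats.truncnorm.rvs(
            a, b, loc=loc, scale=S50_POPULATION_SD, random_state=rng))
        listeners.append(ListenerProfile(
            subject_id=f"S{i + 1:02d}",
            s50=s50,
            slope=float(rng.uniform(*SLOPE_RANGE)),
            lapse=float(rng.uniform(0.0, LAPSE_MAX)),
            rng_seed=int(rng.integers(0, 2**31 - 1)),
        ))
    return listeners


def simulate_word_scores(listener: ListenerProfile, stoi: float,
                         n_words: int, rng: np.random.Generator) -> int:
    """Binomial word score at a given objective intelligibility."""
    return int(rng.binomial(n_words, listener.p_correct(stoi)))


# ---------------------------------------------------------------------------
# stimulus bank: cached STOI per (sentence seed, condition, RT60)
# ---------------------------------------------------------------------------

#: sentence material pools (fixed across listeners, like reusing the same
#: recorded sentence lists): titration and the test/retest lists
TITRATION_SEED_BASE = 10_000
LIST_SEED_BASE = {"test": 20_000, "retest": 30_000}
RATING_SEED_BASE = 40_000


class StimulusBank:
    """Generates, reverberates and scores stimuli once, then caches.

    All listeners hear the same material (as with a recorded sentence
    corpus), so objective scores depend only on (sentence seed, condition,
    RT60) and are shared across the cohort.
    """

    def __init__(self, sample_rate: int = 16_000,
                 wpe_config: WpeConfig | None = None):
        self.sample_rate = sample_rate
        self.wpe_config = wpe_config or WpeConfig()
        self.stft_config = StftConfig(sample_rate=sample_rate)
        self._ir_cache: dict[float, object] = {}
        self._stoi_cache: dict[tuple, float] = {}

    def _ir(self, rt60: float):
        key = round(rt60, 3)
        if key not in self._ir_cache:
            self._ir_cache[key] = simulate_rir(
                study_room(rt60, self.sample_rate), "left")
        return self._ir_cache[key]

    def stoi(self, sentence_seed: int, condition: str,
             rt60: float | None = None) -> float:
        if condition not in CONDITIONS:
            raise ValueError(f"unknown condition {condition!r}")
        if condition == "clean":
            return 1.0  # the reference scored against itself
        reverb = condition.startswith("reverb")
        if reverb:
            if rt60 is None:
                raise ValueError("reverb conditions need an RT60")
            key = (sentence_seed, condition, round(rt60, 3))
        else:
            key = (sentence_seed, condition, None)
        if key not in self._stoi_cache:
            self._compute(sentence_seed, rt60 if reverb else None)
        return self._stoi_cache[key]

    def _compute(self, seed: int, rt60: float | None) -> None:
        """Score all conditions sharing one WPE pass for this stimulus."""
        s = generate_pseudo_sentence(seed, self.sample_rate)
        n = len(s.samples)
        concat = np.tile(s.samples, 5)
        cfg = self.stft_config
        w = self.wpe_config
        hop_s = cfg.hop / cfg.sample_rate
        span = (w.delay * hop_s, (w.delay + w.order) * hop_s)

        if rt60 is None:
            wet, delay, prefix = concat, 0, "clean"
            ref = concat
            pf_rt60 = 1.0
        else:
            ir = self._ir(rt60)
            wet = scipy.signal.fftconvolve(concat, ir.samples)
            delay = ir.direct_index
            prefix = "reverb"
            ref = np.zeros_like(wet)
            ref[delay:delay + len(concat)] = concat
            pf_rt60 = rt60

        frames = analyze(wet, cfg)
        lam = oracle_psd(analyze(ref, cfg) if rt60 is not None else frames)
        res = wpe_dereverb(frames, w, lam)
        removed = np.abs(frames.values - res.frames.values) ** 2
        pf_frames = late_reverb_postfilter(
            res.frames, PostFilterConfig(assumed_rt60=pf_rt60),
            reverb_psd=removed, reverb_span=span)

        def score(audio):
            seg = audio[3 * n + delay:4 * n + delay]
            return compute_stoi(s.samples, seg, self.sample_rate).value

        rkey = round(rt60, 3) if rt60 is not None else None
        if rt60 is not None:
            self._stoi_cache[(seed, "reverb", rkey)] = score(wet)
        self._stoi_cache[(seed, f"{prefix}_wpe", rkey)] = \
            score(synthesize(res.frames))
        self._stoi_cache[(seed, f"{prefix}_wpepf", rkey)] = \
            score(synthesize(pf_frames))


# ---------------------------------------------------------------------------
# titration and crossover protocol
# ---------------------------------------------------------------------------

def titrate_rt60_50(listener: ListenerProfile, bank: StimulusBank,
                    grid: np.ndarray = TITRATION_GRID,
                    sentences_per_rt60: int = 10,
                    rng: np.random.Generator | None = None
                    ) -> ThresholdResult:
    """Find the RT60 at which the listener scores 50 % words correct.

    Ten unprocessed reverberant sentences per grid RT60 (0.4-1.4 s in
    0.1 s steps); the threshold is the linear interpolation between the
    bracketing grid points of the first downward 50 % crossing.
    """
    rng = rng or np.random.default_rng(listener.rng_seed)
    grid = np.asarray(grid, dtype=float)
    percents = np.empty(len(grid))
    for i, rt in enumerate(grid):
        correct = 0
        # the same sentence pool at every RT60: synthetic listeners have
        # no memory, and reusing material isolates the RT60 effect
        for j in range(sentences_per_rt60):
            st = bank.stoi(TITRATION_SEED_BASE + j, "reverb", rt)
            correct += simulate_word_scores(listener, st,
                                            WORDS_PER_SENTENCE, rng)
        percents[i] = 100.0 * correct / (sentences_per_rt60
                                         * WORDS_PER_SENTENCE)
    for i in range(len(grid)):
        if percents[i] == 50.0:
            return ThresholdResult(float(grid[i]), grid, percents)
        if i + 1 < len(grid) and percents[i] > 50.0 >= percents[i + 1]:
            frac = (percents[i] - 50.0) / (percents[i] - percents[i + 1])
            rt = grid[i] + frac * (grid[i + 1] - grid[i])
            return ThresholdResult(float(rt), grid, percents)
    raise ValueError(
        f"no downward 50% crossing on the grid: percents span "
        f"{percents.min():.1f}-{percents.max():.1f}%")


def round_to_stimulus_grid(rt60: float,
                           step: float = STIMULUS_RT60_STEP) -> float:
    """Snap a threshold to the RT60 grid the stimuli exist on."""
    return float(np.round(np.round(rt60 / step) * step, 6))


def run_crossover_study(listeners: list[ListenerProfile],
                        thresholds: dict[str, ThresholdResult],
                        bank: StimulusBank,
                        sentences_per_condition: int = 20) -> pd.DataFrame:
    """Six conditions x test/retest per listener at their RT60_50%.

    Every cell presents ``sentences_per_condition`` sentences (5 words
    each); reverberant cells use the listener's threshold rounded to the
    stimulus grid.  Presentation order of the 12 cells is randomised per
    listener (logged in ``order``); scores are words correct, percent, and
    the rationalised arcsine transform.
    """
    rows = []
    n_words_cell = sentences_per_condition * WORDS_PER_SENTENCE
    for listener in listeners:
        if listener.subject_id not in thresholds:
            raise ValueError(f"missing threshold for {listener.subject_id}")
        rng = np.random.default_rng(listener.rng_seed + 1)
        rt60 = round_to_stimulus_grid(thresholds[listener.subject_id].rt60_50)
        cells = [(c, r) for c in CONDITIONS for r in ("test", "retest")]
        order = rng.permutation(len(cells))
        for pos, cell_idx in enumerate(order):
            condition, replicate = cells[cell_idx]
            reverb = condition.startswith("reverb")
            correct = 0
            for j in range(sentences_per_condition):
                seed = LIST_SEED_BASE[replicate] + j
                st = bank.stoi(seed, condition, rt60 if reverb else None)
                correct += simulate_word_scores(listener, st,
                                                WORDS_PER_SENTENCE, rng)
            rows.append({
                "subject_id": listener.subject_id,
                "condition": condition,
                "replicate": replicate,
                "order": pos,
                "rt60": rt60 if reverb else np.nan,
                "n_words": n_words_cell,
                "n_correct": correct,
                "percent": 100.0 * correct / n_words_cell,
                "rau": rau_transform(correct, n_words_cell),
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------

def rau_transform(n_correct, n_words):
    """Rationalised arcsine units (Studebaker).

    ``theta = arcsin sqrt(x/(n+1)) + arcsin sqrt((x+1)/(n+1))``;
    ``RAU = (146/pi) * theta - 23``.  Maps 0..n to about -23..123 with
    near-uniform variance, linearising scores near the floor and ceiling.
    """
    x = np.asarray(n_correct, dtype=float)
    n = np.asarray(n_words, dtype=float)
    if np.any(x < 0) or np.any(x > n):
        raise ValueError("need 0 <= n_correct <= n_words")
    theta = (np.arcsin(np.sqrt(x / (n + 1)))
             + np.arcsin(np.sqrt((x + 1) / (n + 1))))
    out = (146.0 / np.pi) * theta - 23.0
    return float(out) if out.ndim == 0 else out


def sidak_adjust(p: np.ndarray, m: int | None = None) -> np.ndarray:
    """Sidak familywise adjustment ``1 - (1-p)^m``."""
    p = np.asarray(p, dtype=float)
    m = m if m is not None else p.size
    return 1.0 - (1.0 - p) ** m


def bonferroni_adjust(p: np.ndarray, m: int | None = None) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    m = m if m is not None else p.size
    return np.minimum(1.0, m * p)


def _fit_mixedlm(data: pd.DataFrame, formula: str) -> "smf.mixedlm":
    model = smf.mixedlm(formula, data, groups=data["subject_id"])
    return model.fit(reml=True)


def _wald_f(res, fe_cols: list[int]) -> tuple[float, float]:
    """Wald F test that the given fixed-effect coefficients are all zero."""
    n_full = len(res.params)
    L = np.zeros((len(fe_cols), n_full))
    for r, c in enumerate(fe_cols):
        L[r, c] = 1.0
    wt = res.wald_test(L, scalar=False, use_f=True)
    return float(np.squeeze(wt.statistic)), float(np.squeeze(wt.pvalue))


def fit_condition_lmm(scores: pd.DataFrame) -> LmmResult:
    """RAU ~ condition with a subject random intercept (REML).

    Residuals are i.i.d. (the scaled-identity covariance); the omnibus
    condition effect is a Wald F test on the condition coefficients, and
    all pairwise condition contrasts are Sidak-corrected.
    """
    present = scores["condition"].unique()
    missing = [c for c in CONDITIONS if c not in present]
    if missing:
        raise ValueError(f"conditions missing from the data: {missing}")
    return _lmm_with_pairwise(scores, list(CONDITIONS))


def fit_rt60_lmm(scores: pd.DataFrame,
                 thresholds: dict[str, ThresholdResult]) -> LmmResult:
    """Reverberant conditions only: RAU ~ condition * RT60_50%.

    Tests whether the personal operating point (and its interaction with
    processing) modulates the benefit; in the study it did not.
    """
    reverb_conditions = [c for c in CONDITIONS if c.startswith("reverb")]
    data = scores[scores["condition"].isin(reverb_conditions)].copy()
    if data.empty:
        raise ValueError("no reverberant rows in the scores table")
    data["rt60_50"] = data["subject_id"].map(
        {k: v.rt60_50 for k, v in thresholds.items()})
    if data["rt60_50"].isna().any():
        raise ValueError("missing thresholds for some subjects")
    data["rt60_50_c"] = data["rt60_50"] - data["rt60_50"].mean()
    res = _fit_mixedlm(data, "rau ~ C(condition) + rt60_50_c "
                             "+ C(condition):rt60_50_c")
    fe = pd.DataFrame({"estimate": res.fe_params,
                       "se": res.bse_fe})
    names = list(res.fe_params.index)
    tests = []
    for label, match in [("condition", "C(condition)["),
                         ("rt60_50", "rt60_50_c"),
                         ("condition:rt60_50", ":rt60_50_c")]:
        if label == "condition":
            cols = [i for i, nm in enumerate(names)
                    if nm.startswith(match) and ":" not in nm]
        elif label == "rt60_50":
            cols = [i for i, nm in enumerate(names) if nm == match]
        else:
            cols = [i for i, nm in enumerate(names) if nm.endswith(match)]
        f, p = _wald_f(res, cols)
        tests.append({"effect": label, "F": f, "p": p})
    return LmmResult(fe, float(res.cov_re.iloc[0, 0]), float(res.scale),
                     pd.DataFrame(tests), None)


def _lmm_with_pairwise(scores: pd.DataFrame,
                       conditions: list[str]) -> LmmResult:
    data = scores.copy()
    data["condition"] = pd.Categorical(data["condition"],
                                       categories=conditions, ordered=True)
    res = _fit_mixedlm(data, "rau ~ C(condition)")
    names = list(res.fe_params.index)
    cond_cols = {c: i for i, c in enumerate(names) if "C(condition)" in c}

    # omnibus F on all condition coefficients
    f, p = _wald_f(res, list(cond_cols.values()))
    omnibus = pd.DataFrame([{"effect": "condition", "F": f, "p": p}])

    # pairwise contrasts on the fixed effects
    def coef_vector(cond: str) -> np.ndarray:
        v = np.zeros(len(names))
        key = f"C(condition)[T.{cond}]"
        if key in names:
            v[names.index(key)] = 1.0
        return v

    cov = np.asarray(res.cov_params())[:len(names), :len(names)]
    params = np.asarray(res.fe_params)
    rows = []
    pairs = [(a, b) for i, a in enumerate(conditions)
             for b in conditions[i + 1:]]
    df_resid = len(data) - len(names) - len(data["subject_id"].unique())
    for a, b in pairs:
        c = coef_vector(b) - coef_vector(a)
        est = float(c @ params)
        se = float(np.sqrt(c @ cov @ c))
        t = est / se if se > 0 else np.nan
        p = 2 * scipy.stats.t.sf(abs(t), df_resid)
        rows.append({"pair": f"{a} vs {b}", "estimate": est, "se": se,
                     "t": t, "df": df_resid, "p": p})
    pw = pd.DataFrame(rows)
    pw["p_sidak"] = sidak_adjust(pw["p"].to_numpy(), len(pairs))
    fe = pd.DataFrame({"estimate": res.fe_params, "se": res.bse_fe})
    return LmmResult(fe, float(res.cov_re.iloc[0, 0]), float(res.scale),
                     omnibus, pw)


# ---------------------------------------------------------------------------
# subjective ratings
# ---------------------------------------------------------------------------

def run_rating_block(listeners: list[ListenerProfile],
                     thresholds: dict[str, ThresholdResult],
                     bank: StimulusBank,
                     outcome: str,
                     pairs=RATING_PAIRS,
                     preference_gain: float = 6.0,
                     noise_sd: float = 8.0,
                     seed: int = 0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Paired preference ratings on a 0-100 slider (50 = indifference).

    Listeners rate what they perceive, so the simulated preference is
    driven by the difference in *perceived* intelligibility - each
    listener's own psychometric function evaluated at the two stimuli's
    STOI - passed through a saturating slider map:
    ``50 + 50 tanh(preference_gain * (p_A - p_B)) + noise``, clipped to
    [0, 100].  The psychometric stage compresses differences near ceiling
    (two transparent algorithms on clean speech are indistinguishable
    even if their STOIs differ slightly) and expands them mid-range,
    where the algorithms actually operate.

    Per pair, listener means of test/retest feed a one-sample two-tailed
    t test against 50, Bonferroni-corrected within outcome.  A
    zero-variance degenerate case reports p = 1 with a flag.
    """
    if outcome not in RATING_OUTCOMES:
        raise ValueError(f"unknown outcome {outcome!r}")
    for a, b in pairs:
        if a not in CONDITIONS or b not in CONDITIONS:
            raise ValueError(f"unknown pair label {(a, b)!r}")
    rng = np.random.default_rng(seed)
    records = []
    # each presentation uses one sentence drawn from a small pool, chosen
    # per listener/pair/replicate, as in a session built from recorded lists
    pool = [RATING_SEED_BASE + i for i in range(8)]
    for listener in listeners:
        rt60 = round_to_stimulus_grid(thresholds[listener.subject_id].rt60_50)
        lrng = np.random.default_rng(
            listener.rng_seed + 101 * (RATING_OUTCOMES.index(outcome) + 1))
        for a, b in pairs:
            for replicate in ("test", "retest"):
                sentence_seed = int(lrng.choice(pool))
                st = {}
                for cond in (a, b):
                    st[cond] = bank.stoi(
                        sentence_seed, cond,
                        rt60 if cond.startswith("reverb") else None)
                dp = listener.p_correct(st[a]) - listener.p_correct(st[b])
                score = (50.0 + 50.0 * np.tanh(preference_gain * dp)
                         + rng.normal(0.0, noise_sd))
                records.append({
                    "subject_id": listener.subject_id,
                    "outcome": outcome,
                    "pair": f"{a} vs {b}",
                    "replicate": replicate,
                    "score": float(np.clip(score, 0.0, 100.0)),
                })
    ratings = pd.DataFrame(records)

    tests = []
    for a, b in pairs:
        label = f"{a} vs {b}"
        sub = ratings[ratings["pair"] == label]
        means = sub.groupby("subject_id", sort=True)["score"].mean()
        if np.isclose(means.std(ddof=1), 0.0):
            tests.append({"pair": label, "mean": float(means.mean()),
                          "t": np.nan, "p": 1.0, "degenerate": True})
            continue
        t, p = scipy.stats.ttest_1samp(means, 50.0)
        tests.append({"pair": label, "mean": float(means.mean()),
                      "t": float(t), "p": float(p), "degenerate": False})
    ttable = pd.DataFrame(tests)
    ttable["p_bonferroni"] = bonferroni_adjust(ttable["p"].to_numpy(),
                                               len(pairs))
    return ratings, ttable


def icc3(test: np.ndarray, retest: np.ndarray,
         alpha: float = 0.05) -> IccResult:
    """ICC(3,1): two-way mixed effects, consistency, single measurement.

    ``(MS_between - MS_error) / (MS_between + (k-1) MS_error)`` with
    ``k = 2`` raters (test/retest); the 95 % CI uses the F-distribution
    method.
    """
    test = np.asarray(test, dtype=float)
    retest = np.asarray(retest, dtype=float)
    if test.shape != retest.shape:
        raise ValueError("test and retest must have equal length")
    n = len(test)
    if n < 5:
        raise ValueError("need at least 5 paired measurements")
    k = 2
    data = np.column_stack([test, retest])
    grand = data.mean()
    ss_total = np.sum((data - grand) ** 2)
    ss_rows = k * np.sum((data.mean(axis=1) - grand) ** 2)
    ss_cols = n * np.sum((data.mean(axis=0) - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    ms_rows = ss_rows / (n - 1)
    ms_err = ss_err / ((n - 1) * (k - 1))
    if ms_err == 0.0:  # perfect agreement
        return IccResult(1.0, (1.0, 1.0))
    icc = (ms_rows - ms_err) / (ms_rows + (k - 1) * ms_err)

    f = ms_rows / ms_err
    df1, df2 = n - 1, (n - 1) * (k - 1)
    fl = f / scipy.stats.f.ppf(1 - alpha / 2, df1, df2)
    fu = f * scipy.stats.f.ppf(1 - alpha / 2, df2, df1)
    ci = ((fl - 1) / (fl + k - 1), (fu - 1) / (fu + k - 1))
    return IccResult(float(icc), (float(ci[0]), float(ci[1])))


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def run_full_study(n_listeners: int = 15, seed: int = 0,
                   sentences_per_condition: int = 20,
                   bank: StimulusBank | None = None) -> dict:
    """Complete simulated study: titration, crossover, stats, ratings, ICC."""
    bank = bank or StimulusBank()
    listeners = default_listeners(n_listeners, seed)
    thresholds = {}
    for listener in listeners:
        thresholds[listener.subject_id] = titrate_rt60_50(listener, bank)
    scores = run_crossover_study(listeners, thresholds, bank,
                                 sentences_per_condition)
    lmm_condition = fit_condition_lmm(scores)
    lmm_rt60 = fit_rt60_lmm(scores, thresholds)
    ratings_frames, ttests = [], {}
    for i, outcome in enumerate(RATING_OUTCOMES):
        r, t = run_rating_block(listeners, thresholds, bank, outcome,
                                seed=seed + 1000 + i)
        ratings_frames.append(r)
        ttests[outcome] = t
    ratings = pd.concat(ratings_frames, ignore_index=True)
    wide = ratings.pivot_table(index=["subject_id", "outcome", "pair"],
                               columns="replicate", values="score")
    icc = icc3(wide["test"].to_numpy(), wide["retest"].to_numpy())
    return {
        "listeners": listeners,
        "thresholds": thresholds,
        "scores": scores,
        "lmm_condition": lmm_condition,
        "lmm_rt60": lmm_rt60,
        "ratings": ratings,
        "rating_tests": ttests,
        "icc": icc,
    }
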