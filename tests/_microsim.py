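"""Individual-level stochastic oracle for the cohort engine (test-only).

Simulates each person's yearly path through Well / acute CAD / history /
Dead by sampling the same transition-probability tensor the cohort engine
consumes.  Used to check that the deterministic expected-value update
reproduces event and death counts within Monte-Carlo error.
"""
import numpy as np

WELL, CAD_FIRST, CAD_REPEAT, HISTORY, DEAD = 0, 1, 2, 3, 4


def microsimulate(transitions, counts, horizon, rng):
    """Simulate individuals for ``horizon`` years.

    ``counts`` is an integer (n_ages, 2) array of persons per (initial age,
    sex) stratum.  Returns totals: first events, repeat events, CAD deaths,
    other deaths.
    """
    A, S = counts.shape
    # per-person stratum labels
    a0_list, sex_list = [], []
    for a in range(A):
        for s in range(S):
            n = int(counts[a, s])
            a0_list.append(np.full(n, a))
            sex_list.append(np.full(n, s))
    a0 = np.concatenate(a0_list)
    sex = np.concatenate(sex_list)
    n = len(a0)
    state = np.zeros(n, dtype=np.int8)

    totals = {"first_events": 0.0, "repeat_events": 0.0,
              "cad_deaths": 0.0, "other_deaths": 0.0}
    for t in range(horizon):
        idx = np.minimum(a0 + t, A - 1)
        u = rng.random(n)
        new_state = state.copy()

        well = state == WELL
        p2 = transitions.p_first_cad[t][idx, sex]
        p6 = transitions.p_death_other_well[t][idx, sex]
        ev = well & (u < p2)
        dth = well & (u >= p2) & (u < p2 + p6)
        new_state[ev] = CAD_FIRST
        new_state[dth] = DEAD
        totals["first_events"] += ev.sum()
        totals["other_deaths"] += dth.sum()

        acute_first = state == CAD_FIRST
        acute_repeat = state == CAD_REPEAT
        cf = transitions.p_death_cad[t][idx, sex]
        cf_rep = transitions.case_fatality_repeat[t][idx, sex]
        die1 = acute_first & (u < cf)
        die2 = acute_repeat & (u < cf_rep)
        new_state[acute_first | acute_repeat] = HISTORY
        new_state[die1 | die2] = DEAD
        totals["cad_deaths"] += die1.sum() + die2.sum()

        hist = state == HISTORY
        p5 = transitions.p_repeat_cad[t][idx, sex]
        p8 = transitions.p_death_other_history[t][idx, sex]
        rev = hist & (u < p5)
        hdth = hist & (u >= p5) & (u < p5 + p8)
        new_state[rev] = CAD_REPEAT
        new_state[hdth] = DEAD
        totals["repeat_events"] += rev.sum()
        totals["other_deaths"] += hdth.sum()

        # absorbing age bound: anyone alive past the last table age dies
        beyond = (a0 + t + 1 > A - 1) & (new_state != DEAD)
        totals["other_deaths"] += beyond.sum()
        new_state[beyond] = DEAD
        state = new_state
    return totals


def replicate_microsim(transitions, counts, horizon, n_reps, seed):
    """Mean and SD of microsimulation totals over replicates."""
    rng = np.random.default_rng(seed)
    keys = ("first_events", "repeat_events", "cad_deaths", "other_deaths")
    samples = {k: [] for k in keys}
    for _ in range(n_reps):
        tot = microsimulate(transitions, counts, horizon, rng)
        for k in keys:
            samples[k].append(tot[k])
    return ({k: float(np.mean(v)) for k, v in samples.items()},
            {k: float(np.std(v, ddof=1)) for k, v in samples.items()})
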