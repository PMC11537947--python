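"""Independent straight-line oracles, kept separate from the package code.

``oracle_trial`` re-derives one trial of the saccade field model directly
from the governing equations — field geometry, the eight input envelopes,
the lateral-interaction kernel and the leaky-integrator update — in one
flat function that shares no code with the package.  The remaining
helpers are brute-force reference computations (optimal transport on
sorted samples, exhaustive rank-sum enumeration, Cartesian-product
counting) used to check the analysis statistics.
"""

import itertools
import math

import numpy as np

N = 100
DX = 0.1
DT = 1.0
TAU = 4.0
BETA = 0.09
SIGMA = 0.85
SF = 74.7
M_FRAC = 0.8
THRESHOLD = 0.7
RESET = -30.0
GAMMA = 0.6
AMP = 1.05
PERIOD = 10.0
FIX_ON = 0.0
GAP_ON = 200.0
TGT_ON = 400.0
TIMEOUT = 500.0
NONCENTRAL = 1.0


def _kernel(center):
    out = np.empty(N)
    for i in range(N):
        x = -5.0 + DX * i
        d = abs(x - center) % PERIOD
        d = min(d, PERIOD - d)
        out[i] = AMP * math.exp(-(d * d) / (2.0 * GAMMA * GAMMA))
    return out


def oracle_trial(assignment, target_mm=2.0, vm_reference=1.0):
    """SRT and crossing node for one assignment, from the raw equations."""
    a_ = {k: float(v) for k, v in dict(assignment).items()}
    internal = TGT_ON + a_["internal_onset"]
    positions = np.array([-5.0 + DX * i for i in range(N)])
    noncentral = np.abs(positions) > NONCENTRAL

    w = np.empty((N, N))
    for i in range(N):
        for j in range(N):
            sep = min(abs(i - j), N - abs(i - j)) * DX
            g = SF * math.exp(-(sep * sep) / (2.0 * SIGMA * SIGMA))
            w[i, j] = g  # shift applied below once max is known
    w = (w - M_FRAC * w.max()) * DX

    k_target = _kernel(target_mm)
    k_fix = _kernel(0.0)
    k_prep = _kernel(target_mm) + _kernel(-target_mm)

    def drive(t):
        c = np.zeros(N)
        # 1 visual transient: triangle burst at the target
        r = a_["vt_ror"] / 100.0 * a_["vt_maxval"]
        on = TGT_ON + a_["vt_onset"]
        if t > on and r > 0:
            peak = on + math.ceil(a_["vt_maxval"] / r)
            e = min(r * (t - on), a_["vt_maxval"], a_["vt_maxval"] - r * (t - peak))
            c += k_target * max(0.0, min(e, a_["vt_maxval"]))
        # 2 automated motor: ramp and hold at the target
        r = a_["am_ror"] / 100.0 * a_["am_maxval"]
        on = TGT_ON + a_["am_onset"]
        if t > on:
            c += k_target * min(r * (t - on), a_["am_maxval"])
        # 3 automated fixation: ramp at fixation, linear release from gap
        r = a_["af_ror"] / 100.0 * a_["af_maxval"]
        on = FIX_ON + a_["af_onset"]
        if t > on:
            e = min(r * (min(t, GAP_ON) - on), a_["af_maxval"])
            e = max(0.0, e - r * max(0.0, t - GAP_ON))
            c += k_fix * e
        # 4 voluntary motor: uncapped ramp from the internal onset
        if t > internal:
            c += k_target * (a_["vm_ror"] / 100.0 * vm_reference) * (t - internal)
        # 5 voluntary fixation: ramp from fixation, linear release at internal
        r = a_["vf_ror"] / 100.0 * a_["vf_maxval"]
        if t > FIX_ON:
            e = min(r * (min(t, internal) - FIX_ON), a_["vf_maxval"])
            e = max(0.0, e - r * max(0.0, t - internal))
            c += k_fix * e
        # 6 voluntary preparation: both hemifields, cap in 100 ms
        if t > internal:
            c += k_prep * min(a_["vp_maxval"] / 100.0 * (t - internal), a_["vp_maxval"])
        # 7 inhibitory gate: motor map, windowed proportional release
        held = np.where(noncentral, a_["ig_maxval"], 0.0)
        if t > internal:
            per_ms = np.clip(1.0 - (a_["ig_ror"] / 100.0) * k_target, 0.0, 1.0)
            held = held * per_ms ** (t - internal)
        c -= held
        # 8 peripheral inhibition: motor map, uniform proportional release
        held = np.where(noncentral, a_["pi_maxval"], 0.0)
        if t > internal:
            held = held * (1.0 - a_["pi_ror"] / 100.0) ** (t - internal)
        c -= held
        return c

    u = np.full(N, RESET)
    act = 1.0 / (1.0 + np.exp(-BETA * u))
    n_steps = int(TGT_ON + TIMEOUT)
    for k in range(n_steps):
        u = (1.0 - DT / TAU) * u + (DT / TAU) * (drive(k * DT) + w @ act)
        act = 1.0 / (1.0 + np.exp(-BETA * u))
        masked = np.where(noncentral, act, -np.inf)
        j = int(np.argmax(masked))
        if masked[j] >= THRESHOLD:
            return (k + 1) * DT - TGT_ON, j
    return None, None


def brute_force_wasserstein(xs, ys):
    """Optimal-transport distance between equal-size 1-D samples."""
    xs, ys = np.sort(xs), np.sort(ys)
    assert xs.size == ys.size
    return float(np.mean(np.abs(xs - ys)))


def exact_rank_sum_p(a, b):
    """Two-sided rank-sum p by exhaustive enumeration (tie-free samples)."""
    pooled = list(a) + list(b)
    n_a = len(a)
    ranks = {v: r for r, v in enumerate(sorted(pooled), start=1)}
    observed = sum(ranks[v] for v in a)
    mean = n_a * (len(pooled) + 1) / 2.0
    count = total = 0
    for combo in itertools.combinations(range(len(pooled)), n_a):
        w = sum(r + 1 for r in combo)
        total += 1
        if abs(w - mean) >= abs(observed - mean) - 1e-12:
            count += 1
    return count / total


def brute_force_combinations(level_sets):
    """Cartesian-product count via explicit enumeration of small grids."""
    return sum(1 for _ in itertools.product(*level_sets))
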