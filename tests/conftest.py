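import numpy as np
import pytest

from gaitstride.simulate import GaitSimSpec, simulate_trial


@pytest.fixture(scope="session")
def sim_clean():
    """Noise-free 20 s trial triplet (cadence 170, seed 11)."""
    return simulate_trial(GaitSimSpec(duration=20.0, noise_sd=0.0, seed=11))


@pytest.fixture(scope="session")
def sim_noisy():
    """20 s trial triplet with the default 0.05 g sensor noise."""
    return simulate_trial(GaitSimSpec(duration=20.0, seed=7))


def oracle_force_events(
    v, fs, ic_n=10.0, to_n=25.0, min_stance=0.1, min_sep=0.25
):
    """Brute-force linear-scan reference detector for vGRF thresholding.

    Walks the signal sample by sample: a stance opens at an observed
    up-crossing of ``ic_n`` and must close (drop below ``ic_n``) inside the
    record; its TO is the last sample at/above ``to_n``; stances shorter
    than ``min_stance`` are dropped whole, as are ICs closer than
    ``min_sep`` to the previously kept IC.  Returns [(t_ic, t_to), ...].
    """
    events = []
    last_ic_t = None
    n = len(v)
    i = 0
    while i < n:
        if v[i] >= ic_n and i > 0 and v[i - 1] < ic_n:
            j = i
            while j < n and v[j] >= ic_n:
                j += 1
            if j < n:  # fall observed inside the record
                to_idx = None
                for k in range(j - 1, i - 1, -1):
                    if v[k] >= to_n:
                        to_idx = k
                        break
                if to_idx is not None and (to_idx - i) / fs >= min_stance - 1e-9:
                    t_ic = i / fs
                    if last_ic_t is None or t_ic - last_ic_t >= min_sep - 1e-9:
                        events.append((t_ic, to_idx / fs))
                        last_ic_t = t_ic
            i = j
        else:
            i += 1
    return events


def random_vgrf(rng, fs=500.0):
    """Randomized synthetic vGRF stress signal: Gaussian bumps of widely
    varying amplitude/width, occasional exact-threshold plateaus and
    boundary-touching loads."""
    dur = float(rng.uniform(1.5, 3.5))
    n = int(dur * fs)
    t = np.arange(n) / fs
    v = np.zeros(n)
    for _ in range(int(rng.integers(1, 7))):
        c = rng.uniform(-0.1, dur + 0.1)  # may straddle the record edges
        w = rng.uniform(0.02, 0.5)
        a = rng.uniform(4.0, 900.0)
        v += a * np.exp(-0.5 * ((t - c) / (w / 4.0)) ** 2)
    if rng.random() < 0.3:  # plateau sitting exactly on a threshold
        i0 = int(rng.integers(0, max(1, n - 30)))
        v[i0 : i0 + 15] = float(rng.choice([10.0, 25.0]))
    return v
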