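import numpy as np
import pytest

from actisleep.hypnogram import normalize, resolve_imputed
from actisleep.synthetic import GeneratorConfig, generate


@pytest.fixture(scope="session")
def demo_bundle(tmp_path_factory):
    """A small on-disk synthetic bundle shared across integration tests."""
    outdir = tmp_path_factory.mktemp("bundle")
    cfg = GeneratorConfig(n_participants=40, seed=11)
    paths = generate(cfg, outdir)
    return cfg, paths


def random_runs(rng: np.random.Generator, max_bouts: int = 40):
    """Random alternating sleep/wake runs in minutes, for oracle comparisons.

    Durations are drawn so that anchor (>=30 min) and gap (60 min) boundary
    cases occur often: lengths cluster around 10-90 min with exact 30s and
    60s over-represented.
    """
    n = int(rng.integers(1, max_bouts + 1))
    start = float(rng.integers(0, 120))
    runs = []
    is_sleep = bool(rng.integers(0, 2))
    t = start
    for _ in range(n):
        choice = rng.integers(0, 10)
        if choice < 2:
            dur = 30.0
        elif choice < 4:
            dur = 60.0
        elif choice == 4:
            dur = 61.0
        else:
            dur = float(rng.integers(5, 120))
        runs.append((t, t + dur, is_sleep))
        t += dur
        is_sleep = not is_sleep
    return runs


def brute_force_psp(runs, anchor_minutes=30.0, gap_minutes=60.0):
    """Independent oracle: enumerate every contiguous anchor subsequence that
    forms a valid chain and return the (onset, offset) with the longest span,
    ties to the earliest onset.  Returns None when no anchors exist."""
    anchors = [(s, e) for s, e, sl in runs if sl and e - s >= anchor_minutes]
    best = None
    for i in range(len(anchors)):
        for j in range(i, len(anchors)):
            ok = all(
                anchors[k + 1][0] - anchors[k][1] <= gap_minutes
                for k in range(i, j)
            )
            if not ok:
                continue
            onset, offset = anchors[i][0], anchors[j][1]
            span = offset - onset
            if best is None or span > best[0] or (span == best[0] and onset < best[1]):
                best = (span, onset, offset)
    if best is None:
        return None
    return best[1], best[2]
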