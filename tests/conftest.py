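"""Shared fixtures: a small simulated study, a hand-built miRNA
reference, and independent brute-force oracles."""

from __future__ import annotations

import numpy as np
import pytest

from mirpipe.annotate import MirnaReference
from mirpipe.simulate import SimConfig, run_simulation


@pytest.fixture(scope="session")
def sim():
    """Small simulated study: 10 hairpins (4 clustered, 5 known), two
    ~8k-read libraries."""
    cfg = SimConfig(
        seed=11,
        n_chroms=2,
        chrom_len=150_000,
        n_hairpins=10,
        n_clustered=4,
        n_known=5,
        depth1=8_000,
        depth2=8_000,
    )
    return run_simulation(cfg)


@pytest.fixture(scope="session")
def sim_ref(sim):
    truth, _, _ = sim
    matures, hairpins = truth.known_reference
    placement = {}
    for name, mat in matures.items():
        hp_name = name.replace("miR", "mir")
        pos = hairpins[hp_name].find(mat)
        placement[name] = (hp_name, pos, pos + len(mat))
    return MirnaReference(matures, hairpins, placement)


@pytest.fixture
def toy_ref():
    """Two-mature hand reference with hairpin placements."""
    m1 = "TGAGGTAGTAGGTTGTATAGTT"  # let-7 family mature
    m2 = "TGGAATGTAAAGAAGTATGTAT"  # miR-1 family mature
    hp1 = "CCTAGG" + m1 + "TCTTTCCTATT" + "AACTATACAACCTACTACCTCA"[2:] + "GGAATC"
    hp2 = "GGCACA" + "ATACATACTTCTTTACATTCCA"[2:] + "CATTCGTA" + m2 + "TGTTCC"
    matures = {"toy-miR-a": m1, "toy-miR-b": m2}
    hairpins = {"toy-mir-a": hp1, "toy-mir-b": hp2}
    placement = {
        "toy-miR-a": ("toy-mir-a", hp1.find(m1), hp1.find(m1) + len(m1)),
        "toy-miR-b": ("toy-mir-b", hp2.find(m2), hp2.find(m2) + len(m2)),
    }
    return MirnaReference(matures, hairpins, placement)


# ---------------------------------------------------------------------------
# independent oracles


def levenshtein(a: str, b: str) -> int:
    """Plain full-DP edit distance (substitutions/indels cost 1)."""
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[-1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


def brute_force_match(tag: str, ref: MirnaReference, max_mm: int = 2, end_slack: int = 4):
    """Exhaustive enumeration of every mature x end-offset segment with
    full-DP edit distance; returns (mismatches, name, o5, o3) or None."""
    best = None
    for name in ref.matures:
        mature = ref.matures[name]
        placement = ref.mature_to_hairpin.get(name)
        segs = []
        if placement is not None:
            hp_name, s, e = placement
            hp = ref.hairpins[hp_name]
            for o5 in range(-end_slack, end_slack + 1):
                for o3 in range(-end_slack, end_slack + 1):
                    a, b = s + o5, e + o3
                    if 0 <= a and b <= len(hp) and b - a >= 10:
                        segs.append((o5, o3, hp[a:b]))
        else:
            for o5 in range(0, end_slack + 1):
                for o3 in range(-end_slack, 1):
                    b = len(mature) + o3
                    if b - o5 >= 10:
                        segs.append((o5, o3, mature[o5:b]))
        for o5, o3, seg in segs:
            d = levenshtein(tag, seg)
            if d > max_mm:
                continue
            key = (d, abs(o5), name, o5, o3)
            if best is None or key[:3] < best[:3]:
                best = key
    if best is None:
        return None
    d, _, name, o5, o3 = best
    return d, name, o5, o3


def ac_pvalue_oracle(x: int, y: int, n1: int, n2: int) -> float:
    """Direct finite-summation p-value at 250-digit precision (mpmath):
    both conditioning orientations, doubled smaller tail, min over
    orientations — the definition evaluated naively."""
    import mpmath as mp

    with mp.workdps(250):
        def one_orientation(x, y, n1, n2):
            r = mp.mpf(n2) / n1
            def pmf(k):
                return (
                    r ** k
                    * mp.factorial(x + k)
                    / (mp.factorial(x) * mp.factorial(k) * (1 + r) ** (x + k + 1))
                )
            lower = mp.fsum(pmf(k) for k in range(y + 1))
            upper = 1 - lower + pmf(y)
            return min(1, 2 * min(lower, upper))

        p = min(one_orientation(x, y, n1, n2), one_orientation(y, x, n2, n1))
        return float(p)


def ac_oracle_grid(n1: int, n2: int, xmax: int = 30, ymax: int = 30):
    """One-orientation doubled-tail p-values p[x][y] for the whole
    grid, by direct summation at 250-digit precision (mpmath) with
    cached factorials and powers."""
    import mpmath as mp

    with mp.workdps(250):
        r = mp.mpf(n2) / n1
        one = mp.mpf(1)
        fact = [mp.factorial(k) for k in range(xmax + ymax + 1)]
        rpow = [r**k for k in range(ymax + 1)]
        spow = [(1 + r) ** -(k + 1) for k in range(xmax + ymax + 1)]
        grid = []
        for x in range(xmax + 1):
            pmf = [
                rpow[y] * fact[x + y] / (fact[x] * fact[y]) * spow[x + y]
                for y in range(ymax + 1)
            ]
            row = []
            lower = mp.mpf(0)
            for y in range(ymax + 1):
                lower += pmf[y]
                upper = one - lower + pmf[y]
                row.append(min(one, 2 * min(lower, upper)))
            grid.append(row)
        return grid


def poisson_null_counts(n_pairs: int, total: int, seed: int) -> np.ndarray:
    """Null miRNA count pairs: equal per-miRNA rates in both libraries
    (lognormal around 1e-3 of the library), Poisson sampling."""
    rng = np.random.default_rng(seed)
    rates = np.exp(rng.normal(np.log(1e-3), 0.5, size=n_pairs))
    lam = rates * total  # per-library expected count, ~100 at 1e5
    x = rng.poisson(lam)
    y = rng.poisson(lam)
    return np.stack([x, y], axis=1)
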