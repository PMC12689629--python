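import numpy as np
import pytest

from drugtrace import Spectrum, generate_cohort, generate_library


@pytest.fixture(scope="session")
def small_library():
    library, truth = generate_library(8, seed=11)
    return library, truth


@pytest.fixture(scope="session")
def small_cohort(small_library):
    library, _ = small_library
    table, truth = generate_cohort(library, n_samples=12, n_blanks=2, seed=11)
    return table, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_spectrum_pair(rng, n_max=8, ambiguity=True):
    """A drug spectrum and a jittered analog with a shared precursor shift;
    optionally with extra near-coincident peaks to stress peak assignment."""
    n = int(rng.integers(3, n_max + 1))
    mz = np.sort(rng.uniform(80, 480, n))
    intensity = rng.uniform(5, 100, n)
    precursor = float(rng.uniform(300, 500))
    a = Spectrum("a", precursor, list(zip(mz.tolist(), intensity.tolist())))
    delta = float(rng.uniform(-60, 60))
    shifted = rng.random(n) < 0.5
    mz_b = mz + np.where(shifted, delta, 0.0) + rng.uniform(-0.01, 0.01, n)
    int_b = intensity * np.exp(rng.normal(0, 0.3, n))
    peaks = list(zip(mz_b.tolist(), int_b.tolist()))
    if ambiguity:
        for _ in range(int(rng.integers(0, 3))):
            base = float(rng.choice(mz_b))
            peaks.append(
                (base + float(rng.uniform(-0.015, 0.015)), float(rng.uniform(5, 100)))
            )
    b = Spectrum("b", precursor + delta, peaks[:n_max])
    return a, b


def brute_force_modified_cosine(a, b, frag_tol=0.02):
    """Exhaustive maximum-weight one-to-one assignment over the modified-
    cosine eligibility graph (branch and bound over pair subsets).

    Independent oracle: shares no code with the greedy implementation.
    """
    offset = b.precursor_mz - a.precursor_mz
    ia = np.sqrt(a.intensity)
    ib = np.sqrt(b.intensity)
    norm = float(np.linalg.norm(ia) * np.linalg.norm(ib))
    pairs = []
    for i, mza in enumerate(a.mz):
        for j, mzb in enumerate(b.mz):
            if abs(mza - mzb) <= frag_tol or abs(mzb - mza - offset) <= frag_tol:
                pairs.append((i, j, float(ia[i] * ib[j])))
    best = 0.0

    def recurse(k, used_a, used_b, total):
        nonlocal best
        best = max(best, total)
        if k == len(pairs):
            return
        if total + sum(w for _, _, w in pairs[k:]) <= best:
            return
        i, j, w = pairs[k]
        if i not in used_a and j not in used_b:
            recurse(k + 1, used_a | {i}, used_b | {j}, total + w)
        recurse(k + 1, used_a, used_b, total)

    recurse(0, frozenset(), frozenset(), 0.0)
    return min(best / norm, 1.0) if norm else 0.0
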