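"""Counter-based random-number substreams for the microsimulator.

Every stochastic component of an individual's life history is driven by a
dedicated *purpose stream*: a Philox counter-based generator keyed on
``(seed, purpose)``.  Individual ``i`` always consumes element ``i`` of each
purpose stream, so its draws are a deterministic function of
``(seed, index)``, disjoint from every other individual's, and unchanged by
the cohort size (for ``i < n`` in both runs).  This is what makes the
common-random-numbers contract between screening scenarios exact: toggling a
scenario switch can never perturb draws it does not use.
"""

from __future__ import annotations

import numpy as np

# Fixed purpose ids; never renumber (would silently change all simulations).
PURPOSES = {
    "detection": 0,       # the single uniform reserved for screen detection
    "onset": 1,
    "sojourn_component": 2,
    "sojourn": 3,
    "dwell_g1": 4,        # four gamma uniforms for Dirichlet dwell perturbation
    "dwell_g2": 5,
    "dwell_g3": 6,
    "dwell_g4": 7,
    "clinical_cure": 8,
    "clinical_death": 9,
    "screen_cure": 10,    # reserved: used only by realistic-treatment screen arm
    "screen_death": 11,
}


def purpose_stream(seed: int, purpose: str) -> np.random.Generator:
    """Return the Philox generator for one (seed, purpose) pair."""
    if purpose not in PURPOSES:
        raise KeyError(f"unknown RNG purpose: {purpose!r}")
    ss = np.random.SeedSequence((int(seed), PURPOSES[purpose]))
    return np.random.Generator(np.random.Philox(ss))


def cohort_uniforms(seed: int, purpose: str, n: int) -> np.ndarray:
    """Uniform(0,1) draws for a cohort; element ``i`` belongs to individual ``i``."""
    return purpose_stream(seed, purpose).random(n)
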