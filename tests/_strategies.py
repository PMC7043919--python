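"""Shared hypothesis strategies for the test suite."""

import random

from hypothesis import strategies as st

from gridknot.sampling import sample_grid


def random_grids(min_n=3, max_n=9):
    """Uniform canonical single-component diagrams, seeded via hypothesis."""

    @st.composite
    def build(draw):
        n = draw(st.integers(min_n, max_n))
        seed = draw(st.integers(0, 2**31))
        return sample_grid(n, random.Random(seed))

    return build()
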