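import pytest

from pathosom.fixtures import FixtureSpec, build_paper_cases_kb, generate_random_kb


@pytest.fixture(scope="session")
def paper_kb():
    return build_paper_cases_kb()


@pytest.fixture(scope="session")
def random_kb_factory():
    cache = {}

    def make(seed, **kwargs):
        key = (seed, tuple(sorted(kwargs.items())))
        if key not in cache:
            cache[key] = generate_random_kb(FixtureSpec(seed=seed, **kwargs))
        return cache[key]

    return make
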