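import pytest

from punchcard import design, seqcore


@pytest.fixture(scope="session")
def genome4k() -> str:
    return seqcore.make_genome(4000, 0.5, seed=7).sequence


@pytest.fixture(scope="session")
def genome20k() -> str:
    return seqcore.make_genome(20_000, 0.5, seed=11).sequence


@pytest.fixture(scope="session")
def register10(genome4k) -> design.ReferenceRegister:
    """Single 450 nt register with ten one-sided nick sites."""
    return design.design_register(genome4k, n_sites=10, seed=7)


@pytest.fixture(scope="session")
def register_two_sided() -> design.ReferenceRegister:
    """450 nt register whose ten sites carry guides for both strands."""
    genome = seqcore.make_genome(6000, 0.5, seed=3).sequence
    return design.design_register(genome, n_sites=10, seed=3, two_sided=True)


@pytest.fixture(scope="session")
def mix_register():
    """(detecting matrix, register) pair for N=6 same-register mixtures;
    the register has exactly as many sites as the matrix has columns."""
    from punchcard import mixing

    D = mixing.build_detecting_matrix(6)
    genome = seqcore.make_genome(6000, 0.5, seed=21).sequence
    reg = design.design_register(genome, n_sites=D.M, seed=21)
    return D, reg


@pytest.fixture(scope="session")
def panel5(genome20k) -> design.RegisterPanel:
    """Five orthogonal registers with (10, 5, 6, 5, 6) sites = 32 total."""
    return design.design_panel(
        genome20k, count=5, per_register_sites=[10, 5, 6, 5, 6], seed=11
    )
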