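import pytest

from clotforce import (
    BeamGeometry,
    Material,
    SensorChip,
    SuspensionDesign,
    solve_arm_length,
)


@pytest.fixture(scope="session")
def paper_beam() -> BeamGeometry:
    """Production torsion-beam geometry: 680 um long, 50 thick, 10 wide."""
    return BeamGeometry(length_L=680.0, thickness_a=50.0, width_b=10.0)


@pytest.fixture(scope="session")
def silicon() -> Material:
    return Material()  # 50.9 GPa default


@pytest.fixture(scope="session")
def chip100() -> SensorChip:
    """The 100 N/m production chip with its 100 um stroke."""
    return SensorChip(spring_constant_k=100.0, max_stroke=100.0)


@pytest.fixture(scope="session")
def paper_design(paper_beam, silicon) -> SuspensionDesign:
    """16-beam suspension with the arm length solved for 100 N/m."""
    sol = solve_arm_length(paper_beam, silicon, k_target=100.0)
    return SuspensionDesign(beam=paper_beam, material=silicon, arm_length_C=sol.arm_length_um)
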