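import pytest

from negctrl import ConfoundingStructure, StructuralParams


@pytest.fixture(scope="session")
def conf04() -> ConfoundingStructure:
    """The study's standard confounding structure: rho_UE = rho_UC = 0.4."""
    return ConfoundingStructure(rho_UE=0.4, rho_UC=0.4)


@pytest.fixture(scope="session")
def null_effects() -> StructuralParams:
    """No causal effect of exposure or control; confounder effect 0.2."""
    return StructuralParams(beta1=0.0, beta2=0.0, gamma=0.2)


@pytest.fixture(scope="session")
def exposure_effect() -> StructuralParams:
    """Exposure effect 0.2, genuine negative control; confounder effect 0.2."""
    return StructuralParams(beta1=0.2, beta2=0.0, gamma=0.2)
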