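import pytest

from p2t.fixtures import FixtureParams, generate_snapshot
from p2t.types import TargetRecord


@pytest.fixture(scope="session")
def fixture_bundle():
    """A medium synthetic snapshot plus its ground truth (seed 7)."""
    params = FixtureParams(seed=7)
    snapshot, truth = generate_snapshot(params)
    return params, snapshot, truth


@pytest.fixture(scope="session")
def snapshot(fixture_bundle):
    return fixture_bundle[1]


@pytest.fixture(scope="session")
def truth(fixture_bundle):
    return fixture_bundle[2]


def make_target(symbol="GENE", ensembl_suffix=0, **attrs) -> TargetRecord:
    """Shorthand for a TargetRecord with chosen scoreable attributes."""
    return TargetRecord(
        symbol=symbol,
        ensembl_id=f"ENSG{80_000_000_000 + ensembl_suffix:011d}",
        **attrs,
    )


#: printed attribute vectors for three approved colorectal-cancer targets
#: (disease count, tractability, safety, unique drugs, approved, ph1-4),
#: with their per-run pathway counts and default-preset scores
TABLE4 = {
    "VEGFA": dict(
        record=dict(
            symbol="VEGFA",
            ensembl_id="ENSG00000112715",
            name="Vascular endothelial growth factor A",
            n_associated_diseases=2188,
            tractability_count=5,
            subcellular_location="Secreted",
            n_safety_liabilities=0,
            n_unique_drugs=11,
            n_approved=4,
            n_phase1=0,
            n_phase2=0,
            n_phase3=1,
            n_phase4=4,
        ),
        n_pathways=2,
        default_score=2219.5,
    ),
    "EGFR": dict(
        record=dict(
            symbol="EGFR",
            ensembl_id="ENSG00000146648",
            name="Epidermal growth factor receptor",
            n_associated_diseases=1839,
            tractability_count=7,
            subcellular_location="Cell membrane",
            n_safety_liabilities=2,
            n_unique_drugs=72,
            n_approved=14,
            n_phase1=0,
            n_phase2=0,
            n_phase3=2,
            n_phase4=14,
        ),
        n_pathways=1,
        default_score=1960.0,
    ),
    "PTGS2": dict(
        record=dict(
            symbol="PTGS2",
            ensembl_id="ENSG00000073756",
            name="Prostaglandin-endoperoxide synthase 2",
            n_associated_diseases=1585,
            tractability_count=4,
            subcellular_location="Microsome membrane",
            n_safety_liabilities=25,
            n_unique_drugs=75,
            n_approved=12,
            n_phase1=0,
            n_phase2=0,
            n_phase3=0,
            n_phase4=12,
        ),
        n_pathways=1,
        default_score=1651.0,
    ),
}


@pytest.fixture(scope="session")
def table4_records():
    return {
        sym: (TargetRecord(**spec["record"]), spec["n_pathways"], spec["default_score"])
        for sym, spec in TABLE4.items()
    }
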