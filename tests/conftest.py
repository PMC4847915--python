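import io

import pytest

import adrmine as am

#: seed for the session-wide synthetic dataset; any fixed value works, the
#: statistical tests use 3-standard-error bands.
SYNTH_SEED = 1234


@pytest.fixture(scope="session")
def synth20k():
    """Study-scale synthetic dataset (n = 20000) generated once per session:
    returns (spec, manifest, cases) with cases round-tripped through the CSV
    reader exactly as a real analysis would."""
    spec = am.default_spec(n_cases=20000)
    demo_csv, drug_csv, reac_csv, manifest = am.generate(spec, seed=SYNTH_SEED)
    cases = am.assemble_cases(
        am.read_table(io.StringIO(demo_csv), "DEMO"),
        am.read_table(io.StringIO(reac_csv), "REAC"),
        am.read_table(io.StringIO(drug_csv), "DRUG"),
    )
    return spec, manifest, cases


@pytest.fixture()
def small_cases():
    """Six hand-built cases covering both genders, unknown gender, an
    unmappable age and an empty ADR set."""
    G, C = am.Gender, am.Causality

    def case(cid, gender, age, adrs, drugs):
        return am.Case(cid, gender, age, frozenset(adrs), frozenset(drugs))

    return [
        case("c1", G.FEMALE, "20代", {"suicide attempt", "nausea"},
             {("paroxetine hydrochloride", C.SUSPECTED)}),
        case("c2", G.FEMALE, "70代", {"serotonin syndrome"},
             {("sertraline", C.SUSPECTED)}),
        case("c3", G.MALE, "30代", {"neuroleptic malignant syndrome", "nausea"},
             {("fluvoxamine", C.SUSPECTED)}),
        case("c4", G.MALE, "", {"nausea"},
             {("duloxetine", C.SUSPECTED)}),
        case("c5", G.UNKNOWN, "高齢者", {"rash"},
             {("mirtazapine", C.SUSPECTED)}),
        case("c6", G.FEMALE, "40代", set(),
             {("paroxetine", C.CONCOMITANT)}),
    ]
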