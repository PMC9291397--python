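"""Shared fixtures: compact simulations reused across the test modules."""

from __future__ import annotations

import warnings

import pytest

from peptrace import catalog, pipeline
from peptrace.simulate import (CladePlan, EgtEvent, FamilySpec, MotifLibrary,
                               SpeciesTreeSpec, default_simulation,
                               run_simulation)

SMALL_PLAN = (
    CladePlan("alpha", "Bacteria", 6, 0.5),
    CladePlan("fcb", "Bacteria", 6, 0.0),
    CladePlan("greens", "Eukaryota", 4, 0.0),
)


def small_family_specs(site_rate=0.2, block_loss_rate=0.0):
    common = dict(core_rate_multiplier=0.3, linker_rate_multiplier=1.0,
                  site_rate=site_rate, block_loss_rate=block_loss_rate)
    return [
        FamilySpec("MPP", ("M16", "M16C"), dup_rate=0.1, loss_rate=0.05,
                   hgt_rate=0.05,
                   egt_events=(EgtEvent("alpha", "stem:Eukaryota", 0.3),),
                   **common),
        FamilySpec("OOP", ("M3",), dup_rate=0.15, loss_rate=0.05, hgt_rate=0.05,
                   egt_events=(EgtEvent("fcb", "stem:Eukaryota", 0.3),),
                   **common),
    ]


@pytest.fixture(scope="session")
def small_sim():
    spec = SpeciesTreeSpec(clade_plan=SMALL_PLAN, seed=11)
    return run_simulation(spec, small_family_specs(), seed=11, n_background=2)


@pytest.fixture(scope="session")
def small_catalog(small_sim):
    """Full catalogue run on the small fixture (shared, it is the slow bit)."""
    from peptrace import phylo
    proteomes = catalog.records_from_fixture(small_sim.proteome_records())
    comps = [catalog.FamilyComposition("MPP", ("M16", "M16C")),
             catalog.FamilyComposition("OOP", ("M3",))]
    clade_of = small_sim.taxonomy.set_index("species_id")["clade"].to_dict()
    ctree = phylo.clade_tree_from_species(small_sim.species_tree, clade_of)
    refs = pipeline.pick_references(small_sim)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return catalog.reconstruct_families(
            proteomes, refs, comps, small_sim.motifs.consensus, clade_of, ctree)


@pytest.fixture(scope="session")
def default_sim():
    return default_simulation(seed=42)


@pytest.fixture(scope="session")
def motif_library():
    return MotifLibrary.default()
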