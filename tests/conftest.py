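import numpy as np
import pandas as pd
import pytest

from gwasbasis.basis import build_basis
from gwasbasis.harmonise import ReferencePanel, SummaryStats, variant_ids
from gwasbasis.shrinkage import compute_weights
from gwasbasis.simulate import SimulationScenario, simulate_panel, simulate_traits


@pytest.fixture(scope="session")
def small_system():
    """A complete simulated system: panel, studies, weights, fitted basis."""
    scenario = SimulationScenario(n_snps=2_000, n_blocks=40, n_traits=8,
                                  seed=11)
    rng = np.random.default_rng(11)
    panel = simulate_panel(scenario, rng)
    studies, truth = simulate_traits(scenario, panel, rng)
    weights = compute_weights(studies, panel)
    basis = build_basis(studies, weights)
    return {
        "scenario": scenario,
        "panel": panel,
        "studies": studies,
        "truth": truth,
        "weights": weights,
        "basis": basis,
    }


def make_panel(records, ld=None):
    """Tiny hand-written panel from (chrom, pos, ref, alt, freq, block)."""
    df = pd.DataFrame(records,
                      columns=["chrom", "pos", "ref", "alt", "alt_freq",
                               "block"])
    df["chrom"] = df["chrom"].astype(str)
    df.index = variant_ids(df)
    return ReferencePanel(variants=df, ld=ld)


def make_study(records, trait_id="study", aligned=False):
    """Tiny summary-stats table from (chrom, pos, ref, alt, beta, se)."""
    df = pd.DataFrame(records,
                      columns=["chrom", "pos", "ref", "alt", "beta", "se"])
    df["chrom"] = df["chrom"].astype(str)
    df.index = variant_ids(df)
    return SummaryStats(trait_id=trait_id, data=df, aligned=aligned)


@pytest.fixture
def toy_panel():
    return make_panel([
        ("1", 100, "A", "G", 0.30, "b1"),
        ("1", 200, "C", "T", 0.10, "b1"),
        ("1", 300, "G", "T", 0.50, "b1"),
        ("2", 100, "A", "C", 0.25, "b2"),
        ("2", 200, "T", "G", 0.40, "b2"),
        ("6", 25_000_000, "A", "G", 0.20, "b3"),
    ])
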