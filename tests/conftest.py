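import numpy as np
import pandas as pd
import pytest

import viroquant as vq


@pytest.fixture(scope="session")
def small_panel() -> vq.LinePanel:
    """100 lines x 300 sites with modest LD and missingness."""
    spec = vq.PanelSpec(
        n_lines=100, n_sites=300, seed=11, ld_copy_prob=0.6, missing_rate=0.03, het_rate=0.01
    )
    return vq.generate_panel(spec)


@pytest.fixture(scope="session")
def gaussian_pheno(small_panel):
    """Survival phenotypes with one planted locus and known components."""
    sites = vq.filter_sites(small_panel)
    # pick a reasonably common site for the planted effect
    freqs = (small_panel.genotypes[sites] == 2).mean()
    site = freqs.sub(0.4).abs().idxmin()
    model = vq.GeneticModel(
        causal_loci=[vq.CausalLocus(site, "dcv", a=1.2)],
        traits={"dcv": vq.TraitDef("observed-survival", beta=6.0, v_line_poly=0.5, v_vial=0.3, v_resid=1.0)},
    )
    pheno, truth = vq.simulate_gaussian_trait(
        small_panel, model, "dcv", n_vials=4, flies_per_vial=10, seed=7
    )
    return pheno, truth, site


@pytest.fixture(scope="session")
def binomial_pheno(small_panel):
    model = vq.GeneticModel(
        traits={"sigma": vq.TraitDef("logit-infection", beta=0.0, v_line_poly=1.5, v_resid=1.0)}
    )
    pheno, truth = vq.simulate_binomial_trait(
        small_panel, model, "sigma", n_vials=4, flies_per_vial=15, seed=13
    )
    return pheno, truth


def make_line_values(panel, values):
    lv = pd.DataFrame({"line_id": panel.line_ids, "value": np.asarray(values, dtype=float)})
    return lv
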