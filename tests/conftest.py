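import numpy as np
import pytest

from coralhgt.types import TaxonEntry, TaxonomyMap


@pytest.fixture
def taxonomy():
    """Small mixed taxonomy: corals, other metazoans, bacteria, algae."""
    entries = {
        "q": TaxonEntry("Acropora_digitifera", "Scleractinia_o", "Cnidaria_p", "CoralComplex"),
        "q2": TaxonEntry("Seriatopora_sp", "Scleractinia_o", "Cnidaria_p", "CoralRobust"),
        "anem": TaxonEntry("Nematostella_vectensis", "Actiniaria_o", "Cnidaria_p", "Actiniaria"),
        "fan": TaxonEntry("Gorgonia_sp", "Alcyonacea_o", "Cnidaria_p", "OtherAnthozoa"),
        "m1": TaxonEntry("Homo_sapiens", "Primates", "Chordata", "OtherMetazoa"),
        "m2": TaxonEntry("Mus_musculus", "Rodentia", "Chordata", "OtherMetazoa"),
        "m3": TaxonEntry("Drosophila_melanogaster", "Diptera", "Arthropoda", "OtherMetazoa"),
        "b1": TaxonEntry("Escherichia_coli", "Enterobacterales", "Proteobacteria", "Bacteria"),
        "b2": TaxonEntry("Bacillus_subtilis", "Bacillales", "Firmicutes", "Bacteria"),
        "b3": TaxonEntry("Vibrio_sp", "Vibrionales", "Proteobacteria", "Bacteria"),
        "ca1": TaxonEntry("Emiliania_huxleyi", "Isochrysidales", "Haptophyta", "CAAlgae"),
        "dino1": TaxonEntry("Symbiodinium_minutum", "Suessiales", "Dinoflagellata_p", "Dinoflagellata"),
        "viri1": TaxonEntry("Chlorella_variabilis", "Chlorellales", "Chlorophyta", "Viridiplantae"),
    }
    tax = TaxonomyMap()
    for key, entry in entries.items():
        tax.add(key, entry)
    return tax


@pytest.fixture
def rng():
    return np.random.default_rng(42)
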