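import pandas as pd
import pytest

import somdriver as sd
from somdriver.simulate import cds_length_table, write_maf


@pytest.fixture(scope="session")
def code_table():
    return sd.enumerate_codon_mutation_space()


@pytest.fixture(scope="session")
def planted_dataset(tmp_path_factory):
    """Default study conditions: 200 neutral + 5 OG-like + 5 TSG-like genes.

    Simulates the reference table and cohort MAF, writes them through the
    real file formats, and runs the full two-step pipeline once.
    """
    tmp = tmp_path_factory.mktemp("planted")
    config = sd.SimulationConfig(seed=1)
    mutations, truth = sd.simulate_reference(config)
    lengths = cds_length_table(truth)

    ref_path = tmp / "reference.tsv"
    mutations.to_csv(ref_path, sep="\t", index=False)
    ref_df, ref_report = sd.read_mutation_table(ref_path, lengths)
    model = sd.build_reference(ref_df, lengths)

    maf = sd.simulate_cohort_maf(config, truth)
    maf_path = tmp / "cohort.maf"
    write_maf(maf, maf_path)
    cohort, cohort_report = sd.read_maf(maf_path, lengths)
    results = sd.run_detection(cohort, model)
    return {
        "config": config,
        "truth": truth,
        "lengths": lengths,
        "model": model,
        "cohort": cohort,
        "results": results,
        "ref_report": ref_report,
        "cohort_report": cohort_report,
    }


@pytest.fixture()
def toy_maf(tmp_path):
    """Three-row MAF: one missense, one nonsense, one silent."""
    path = tmp_path / "toy.maf"
    rows = pd.DataFrame(
        {
            "Hugo_Symbol": ["GENE1", "GENE1", "GENE2"],
            "Tumor_Sample_Barcode": ["S1", "S2", "S1"],
            "Variant_Classification": ["Missense_Mutation", "Nonsense_Mutation", "Silent"],
            "HGVSc": ["c.100A>G", "c.50C>T", "c.9G>A"],
        }
    )
    rows.to_csv(path, sep="\t", index=False)
    return path
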