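import numpy as np
import pytest

from tlpcensus import synthetic_data as synth


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def census_bundle(tmp_path_factory):
    """Default census composition (38 typical + 4 TLP-kinase) with files on
    disk plus the locus inputs, shared across pipeline tests."""
    from tlpcensus.io_formats import write_fasta

    d = tmp_path_factory.mktemp("bundle")
    records, truths = synth.generate_census_bundle(seed=11)
    write_fasta(records, d / "proteins.fasta")
    gff_text, rep_text, locus_truth = synth.generate_locus(seed=11)
    (d / "locus.gff3").write_text(gff_text)
    (d / "repeats.tsv").write_text(rep_text)
    return {
        "dir": d,
        "fasta": d / "proteins.fasta",
        "gff": d / "locus.gff3",
        "repeats": d / "repeats.tsv",
        "records": records,
        "truths": truths,
        "locus_truth": locus_truth,
    }
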