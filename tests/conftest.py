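import numpy as np
import pytest

from targetmr import datasets
from targetmr.io import write_associations, write_ld_matrix
from targetmr.select import align_to_increasing, harmonize_pair


@pytest.fixture
def il6_records():
    """Published instrument associations with standardized IL-6 level."""
    return datasets.il6_exposure_associations()


@pytest.fixture
def il6_candidates():
    """Exposure candidates including the palindromic placeholder variant."""
    return datasets.il6_exposure_associations(include_palindromic=True)


@pytest.fixture
def ld_full():
    return datasets.il6r_ld_matrix(include_palindromic=True)


@pytest.fixture
def chd_pairs(il6_records):
    """Harmonized, exposure-increasing-aligned pairs for the CHD outcome."""
    chd = {r.rsid: r for r in datasets.outcome_associations("coronary_heart_disease")}
    return [align_to_increasing(harmonize_pair(e, chd[e.rsid])) for e in il6_records]


@pytest.fixture
def exposure_tsv(tmp_path, il6_candidates):
    path = tmp_path / "exposure.tsv"
    write_associations(il6_candidates, path)
    return path


@pytest.fixture
def ld_tsv(tmp_path, ld_full):
    path = tmp_path / "ld.tsv"
    write_ld_matrix(ld_full, path)
    return path


@pytest.fixture
def outcome_tsv_factory(tmp_path):
    def _make(trait):
        path = tmp_path / f"{trait}.tsv"
        write_associations(datasets.outcome_associations(trait), path)
        return path

    return _make
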