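import numpy as np
import pandas as pd
import pytest

from genefam.qpcr import CtDataset


@pytest.fixture
def make_ct_dataset():
    """Factory: build a CtDataset from per-sample replicate dCt values.

    The reference gene is held at Ct 20 in every well, so the target Ct is
    20 + dCt and the per-replicate paired dCt equals the requested values.
    """

    def build(dct_by_sample, gene="GeneX", reference="actin", calibrator=None):
        records = []
        for sample, dcts in dct_by_sample.items():
            for i, dct in enumerate(dcts, start=1):
                records.append(
                    {"gene": reference, "sample": sample, "condition": sample,
                     "replicate": i, "Ct": 20.0}
                )
                records.append(
                    {"gene": gene, "sample": sample, "condition": sample,
                     "replicate": i, "Ct": 20.0 + dct}
                )
        calibrator = calibrator or next(iter(dct_by_sample))
        return CtDataset(
            wells=pd.DataFrame.from_records(records),
            reference_gene=reference,
            calibrator_sample=calibrator,
        )

    return build


@pytest.fixture
def rng():
    return np.random.default_rng(20130524)
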