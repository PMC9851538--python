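import numpy as np
import pandas as pd
import pytest

from organoidkit import FeatureTable


def build_table(
    signal: dict[str, list[float]],
    groups: list[str],
    analyte_ids: dict[str, str] | None = None,
    classes: dict[str, str] | None = None,
) -> FeatureTable:
    """Small hand-built feature table; NaN encodes missing.

    ``signal`` maps feature id -> per-sample values; ``groups`` assigns
    each sample a group label ("QC" marks QC injections).
    """
    features = list(signal)
    n = len(groups)
    sample_ids = [f"S{i+1}" for i in range(n)]
    sig = pd.DataFrame(
        {f: np.asarray(v, dtype=float) for f, v in signal.items()},
        index=sample_ids,
    )
    meta = pd.DataFrame(
        {"group": groups, "is_qc": [g == "QC" for g in groups]}, index=sample_ids
    )
    fmeta = pd.DataFrame(
        {
            "analyte_id": [
                (analyte_ids or {}).get(f, f) for f in features
            ],
            "class": [(classes or {}).get(f, "metabolite") for f in features],
        },
        index=features,
    )
    return FeatureTable(signal=sig, sample_meta=meta, feature_meta=fmeta)


@pytest.fixture
def toy_table() -> FeatureTable:
    """4 study samples (2 DD + 2 DN) and 3 QC injections, 3 features."""
    return build_table(
        {
            "A": [1.0, 2.0, 3.0, 4.0, 10.0, 10.0, 10.0],
            "B": [2.0, 2.0, 4.0, 4.0, 9.0, 10.0, 11.0],
            "C": [5.0, 6.0, 7.0, 8.0, 5.0, 10.0, 15.0],
        },
        ["DD", "DD", "DN", "DN", "QC", "QC", "QC"],
    )
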