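"""Tab-separated input/output with config provenance headers.

Every table a pipeline run writes carries the effective configuration hash
in a leading comment line; readers can verify the hash so that stages are
never chained across mismatched intermediate files.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional, Tuple

import pandas as pd

from .annotate import FeatureTable

HEADER_PREFIX = "# lipidquant-config: "


def config_hash(config_dict: dict) -> str:
    """Stable short hash of a configuration mapping."""
    canon = json.dumps(config_dict, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:12]


def write_table(
    df: pd.DataFrame, path, cfg_hash: Optional[str] = None, index: bool = True
) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        if cfg_hash is not None:
            fh.write(HEADER_PREFIX + cfg_hash + "\n")
        df.to_csv(fh, sep="\t", index=index)


def read_table(
    path, expect_hash: Optional[str] = None, index_col=0
) -> pd.DataFrame:
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
        has_header = first.startswith(HEADER_PREFIX)
        found = first[len(HEADER_PREFIX):].strip() if has_header else None
        if expect_hash is not None and found != expect_hash:
            raise ValueError(
                f"{path}: config hash mismatch (found {found!r}, "
                f"expected {expect_hash!r}); refusing stale intermediate"
            )
        fh.seek(0)
        return pd.read_csv(
            fh, sep="\t", comment="#", index_col=index_col
        )


def write_feature_table(
    table: FeatureTable, features_path, samples_path, cfg_hash=None
) -> None:
    combined = table.features.join(table.intensities)
    write_table(combined, features_path, cfg_hash)
    write_table(table.samples, samples_path, cfg_hash)


def read_feature_table(
    features_path, samples_path, expect_hash=None
) -> FeatureTable:
    combined = read_table(features_path, expect_hash)
    samples = read_table(samples_path, expect_hash)
    meta_cols = ["mz", "rt_min", "ion_mode"]
    return FeatureTable(
        features=combined[meta_cols],
        intensities=combined.drop(columns=meta_cols),
        samples=samples,
    )
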