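"""Bundled reference data.

The package ships the published curated list of non-redundant anthozoan
genes derived via horizontal transfer (41 events, each with its ancestor
assignment, confirmation support and donor source label), transcribed into
TSV. It is the fixed point the event bookkeeping is checked against.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

_EVENTS_FILE = "hgt_events_published.tsv"


def published_hgt_events() -> pd.DataFrame:
    """The curated non-redundant transfer-event table.

    Columns: ``no`` (event number), ``ancestor`` (Coral | Anthozoa),
    ``genes`` (representative query sequence), ``protein_product``,
    ``support`` (confirmation UFboot %), ``source`` (donor label).
    """
    ref = resources.files("coralhgt.data").joinpath(_EVENTS_FILE)
    with ref.open() as handle:
        df = pd.read_csv(handle, sep="\t")
    df["ancestor"] = df["ancestor"].astype(str)
    return df


def summarize_events(events: pd.DataFrame) -> dict[str, int]:
    """Event bookkeeping: total events and the ancestor split."""
    ancestors = events["ancestor"]
    return {
        "total": int(len(events)),
        "anthozoa": int((ancestors == "Anthozoa").sum()),
        "coral": int((ancestors == "Coral").sum()),
    }
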