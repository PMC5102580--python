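"""Event tables: typed, timed experimental events.

An event table is a :class:`pandas.DataFrame` with one row per event and the
columns

======================  =====================================================
``onset_s``             event onset, seconds from recording start
``offset_s``            event offset, seconds (stimulus offset = next onset)
``kind``                ``stimulus`` | ``gap`` | ``blink``
``category``            stimulus category of the host trial:
                        ``face`` | ``nonface`` | ``animal`` | ``NA``
``subtype``             ``spontaneous`` | ``voluntary`` (blinks),
                        ``black`` | ``gray`` (gaps), ``NA`` otherwise
``ramp``                ``abrupt`` | ``gradual`` (gaps), ``NA`` otherwise
``trial_index``         0-based trial counter across the session
``block_index``         0-based block counter
======================  =====================================================

Tables round-trip losslessly through tab-separated text files.
"""

from __future__ import annotations

import pandas as pd

COLUMNS = [
    "onset_s",
    "offset_s",
    "kind",
    "category",
    "subtype",
    "ramp",
    "trial_index",
    "block_index",
]

KINDS = {"stimulus", "gap", "blink"}
CATEGORIES = {"face", "nonface", "animal", "NA"}
SUBTYPES = {"spontaneous", "voluntary", "black", "gray", "NA"}
RAMPS = {"abrupt", "gradual", "NA"}


def empty_table() -> pd.DataFrame:
    return pd.DataFrame({c: pd.Series(dtype=t) for c, t in zip(
        COLUMNS,
        [float, float, object, object, object, object, int, int],
    )})


def validate_events(events: pd.DataFrame) -> None:
    """Raise ``ValueError`` on a malformed event table."""
    missing = [c for c in COLUMNS if c not in events.columns]
    if missing:
        raise ValueError(f"event table missing columns: {missing}")
    if len(events) == 0:
        return
    if not set(events["kind"]).issubset(KINDS):
        raise ValueError(f"unknown kind values: {set(events['kind']) - KINDS}")
    if not set(events["category"]).issubset(CATEGORIES):
        raise ValueError("unknown category values")
    if not set(events["subtype"]).issubset(SUBTYPES):
        raise ValueError("unknown subtype values")
    bad = events[events["onset_s"] >= events["offset_s"]]
    if len(bad):
        raise ValueError(f"{len(bad)} events with onset >= offset")


def write_events(events: pd.DataFrame, path) -> None:
    events.to_csv(path, sep="\t", index=False)


def read_events(path) -> pd.DataFrame:
    events = pd.read_csv(
        path, sep="\t",
        dtype={"kind": str, "category": str, "subtype": str, "ramp": str},
        keep_default_na=False,
    )
    validate_events(events)
    return events


def select(events: pd.DataFrame, kind=None, category=None, subtype=None) -> pd.DataFrame:
    """Filter an event table by kind / category / subtype (each optional)."""
    mask = pd.Series(True, index=events.index)
    if kind is not None:
        mask &= events["kind"] == kind
    if category is not None:
        cats = [category] if isinstance(category, str) else list(category)
        mask &= events["category"].isin(cats)
    if subtype is not None:
        subs = [subtype] if isinstance(subtype, str) else list(subtype)
        mask &= events["subtype"].isin(subs)
    return events[mask]
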