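"""Cytometry event tables: reading, transforms, gating, capping, merging.

The central container is :class:`EventTable`: an events x channels matrix for
one sample (or a merged set of samples) together with its transform state.
Rule-based gates replace manual gating: every gate returns a
:class:`GateReport` so the event bookkeeping is auditable.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .transforms import (
    ArcsinhTransform,
    LogicleParams,
    LogicleTransform,
    estimate_logicle_params,
)

__all__ = [
    "EventTable",
    "GateReport",
    "read_events",
    "write_events_csv",
    "arcsinh_transform",
    "auto_logicle_transform",
    "gate_events",
    "cap_events",
    "merge_samples",
]

_TRANSFORM_STATES = ("raw", "logicle", "arcsinh")


@dataclass
class EventTable:
    """Events x channels matrix for one cytometry sample.

    Attributes
    ----------
    sample_id : str
    data : pandas.DataFrame
        Events x channels, numeric.  Column order is the panel order.
    transform_state : {"raw", "logicle", "arcsinh"}
    transform_params : dict
        Per-channel parameter record; empty iff ``transform_state == "raw"``.
    stained : bool
        False for unstained control samples.
    truth_labels : numpy.ndarray or None
        Per-event ground-truth labels (synthetic cohorts only).
    provenance : numpy.ndarray or None
        Per-event originating sample id (set by :func:`merge_samples`).
    """

    sample_id: str
    data: pd.DataFrame
    transform_state: str = "raw"
    transform_params: dict = field(default_factory=dict)
    stained: bool = True
    truth_labels: np.ndarray | None = None
    provenance: np.ndarray | None = None

    def __post_init__(self):
        if self.transform_state not in _TRANSFORM_STATES:
            raise ValueError(f"unknown transform_state {self.transform_state!r}")
        cols = list(self.data.columns)
        if len(set(cols)) != len(cols):
            raise ValueError("duplicate channel names in event table")
        if (self.transform_state == "raw") != (not self.transform_params):
            raise ValueError("transform_state raw iff transform_params empty")
        if self.transform_state != "raw" and self.data.isna().any().any():
            raise ValueError("missing values after transform")
        for attr in ("truth_labels", "provenance"):
            v = getattr(self, attr)
            if v is not None and len(v) != len(self.data):
                raise ValueError(f"{attr} length does not match event count")

    @property
    def channels(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_events(self) -> int:
        return len(self.data)

    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def take(self, idx: np.ndarray) -> "EventTable":
        """Row subset preserving all per-event side information."""
        return replace(
            self,
            data=self.data.iloc[idx].reset_index(drop=True),
            truth_labels=None if self.truth_labels is None else np.asarray(self.truth_labels)[idx],
            provenance=None if self.provenance is None else np.asarray(self.provenance)[idx],
        )


@dataclass(frozen=True)
class GateReport:
    rule: str
    channel: str | None
    threshold: float | None
    events_in: int
    events_out: int

    def __post_init__(self):
        if not 0 <= self.events_out <= self.events_in:
            raise ValueError("GateReport counts inconsistent")

    @property
    def events_removed(self) -> int:
        return self.events_in - self.events_out

    def to_json(self) -> str:
        return json.dumps(
            {
                "rule": self.rule,
                "channel": self.channel,
                "threshold": self.threshold,
                "events_in": self.events_in,
                "events_out": self.events_out,
            }
        )


def read_events(path, format: str | None = None, sample_id: str | None = None) -> EventTable:
    """Read a raw event table from CSV (headered) or FCS 3.0/3.1.

    ``format`` is inferred from the file suffix when not given.
    """
    path = Path(path)
    if format is None:
        format = "fcs" if path.suffix.lower() == ".fcs" else "csv"
    if sample_id is None:
        sample_id = path.stem
    if format == "fcs":
        from .fcs import read_fcs

        channels, values = read_fcs(path)
        data = pd.DataFrame(values, columns=channels)
    elif format == "csv":
        if path.stat().st_size == 0:
            raise OSError(f"{path}: empty file")
        data = pd.read_csv(path)
        if not all(np.issubdtype(d, np.number) for d in data.dtypes):
            raise ValueError(f"{path}: non-numeric channel values")
    else:
        raise ValueError(f"unknown format {format!r}")
    return EventTable(sample_id=sample_id, data=data)


def write_events_csv(table: EventTable, path) -> None:
    table.data.to_csv(path, index=False)


def arcsinh_transform(table: EventTable, cofactor: float = 5.0) -> EventTable:
    """asinh(x / cofactor) on every channel; requires a raw table."""
    if table.transform_state != "raw":
        raise ValueError("arcsinh_transform expects a raw table")
    tr = ArcsinhTransform(cofactor=cofactor).fit(table.values())
    out = pd.DataFrame(tr.transform(table.values()), columns=table.channels)
    params = {ch: {"method": "arcsinh", "cofactor": cofactor} for ch in table.channels}
    return replace(table, data=out, transform_state="arcsinh", transform_params=params)


def _apply_logicle(table: EventTable, params: dict) -> EventTable:
    X = table.values()
    out = np.empty_like(X)
    for j, ch in enumerate(table.channels):
        p = params[ch]
        if p["method"] == "logicle":
            out[:, j] = LogicleTransform(params=p["params"]).transform(X[:, j])
        else:
            out[:, j] = np.arcsinh(X[:, j] / p["cofactor"])
    data = pd.DataFrame(out, columns=table.channels)
    return replace(table, data=data, transform_state="logicle", transform_params=params)


def auto_logicle_transform(
    stained: EventTable,
    unstained: EventTable | None = None,
    cofactor_fallback: float = 150.0,
):
    """Automatic logicle transform with the joint stained/unstained convention.

    Parameters are estimated per channel from the *merged* stained and
    unstained events so that matched control samples undergo the identical
    transform, then applied to each table separately.  Channels on which the
    logicle parameterization is degenerate (all-identical values, or no
    positive values) fall back to arcsinh with ``cofactor_fallback``; the
    fallback is recorded in the returned parameter record.

    Returns ``(stained_t, unstained_t, params)``; ``unstained_t`` is ``None``
    when no unstained table was given.
    """
    if stained.transform_state != "raw":
        raise ValueError("auto_logicle_transform expects raw tables")
    if unstained is not None:
        if unstained.transform_state != "raw":
            raise ValueError("auto_logicle_transform expects raw tables")
        if unstained.channels != stained.channels:
            raise ValueError("stained and unstained panels differ")
        merged = np.vstack([stained.values(), unstained.values()])
    else:
        merged = stained.values()

    params: dict[str, dict] = {}
    for j, ch in enumerate(stained.channels):
        p = estimate_logicle_params(merged[:, j])
        if p is None:
            params[ch] = {"method": "arcsinh", "cofactor": cofactor_fallback}
        else:
            params[ch] = {"method": "logicle", "params": p}

    stained_t = _apply_logicle(stained, params)
    unstained_t = None if unstained is None else _apply_logicle(unstained, params)
    return stained_t, unstained_t, params


_GATE_RULES = ("viability_below", "channel_above", "channel_below", "not_doublet")


def gate_events(
    table: EventTable,
    rule: str,
    channel: str | None = None,
    threshold: float | None = None,
):
    """Apply one strict-inequality event gate; returns (table, GateReport).

    Rules
    -----
    ``channel_above`` / ``channel_below``
        Keep events strictly above / below ``threshold`` on ``channel``
        (e.g. the CD45 > 0.5 leukocyte gate on the arcsinh scale).
    ``viability_below``
        Keep events with viability stain strictly below ``threshold``
        (dead cells take up the stain).
    ``not_doublet``
        Ratio gate on area-vs-height proxy channels: keeps events with
        ``area/height < threshold`` where ``channel`` names the area channel
        and a matching ``*_H``/``-H`` height channel exists; a no-op with a
        warning otherwise.
    """
    if rule not in _GATE_RULES:
        raise ValueError(f"unknown gate rule {rule!r}")
    if table.transform_state == "raw":
        raise ValueError("gate_events expects a transformed table")
    n_in = table.n_events

    if rule == "not_doublet":
        height = None
        if channel is not None:
            for suffix_a, suffix_h in (("_A", "_H"), ("-A", "-H")):
                if channel.endswith(suffix_a):
                    cand = channel[: -len(suffix_a)] + suffix_h
                    if cand in table.data.columns:
                        height = cand
        if channel is None or channel not in table.data.columns or height is None:
            warnings.warn(
                "not_doublet gate: no area/height channel pair present; gate is a no-op"
            )
            return table, GateReport(rule, channel, threshold, n_in, n_in)
        ratio = table.data[channel].to_numpy() / table.data[height].to_numpy()
        keep = ratio < threshold
    else:
        if channel not in table.data.columns:
            raise KeyError(f"unknown channel {channel!r}")
        x = table.data[channel].to_numpy()
        if rule == "channel_above":
            keep = x > threshold
        else:  # channel_below, viability_below
            keep = x < threshold

    idx = np.flatnonzero(keep)
    out = table.take(idx)
    return out, GateReport(rule, channel, threshold, n_in, int(keep.sum()))


def cap_events(table: EventTable, cap: int, seed: int = 0) -> EventTable:
    """Uniform seeded subsample without replacement to at most ``cap`` events.

    Event order of the survivors is preserved.
    """
    if cap < 1:
        raise ValueError(f"cap must be >= 1, got {cap}")
    if table.n_events <= cap:
        return table
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(table.n_events, size=cap, replace=False))
    return table.take(idx)


def merge_samples(tables: list[EventTable]) -> EventTable:
    """Row-concatenate tables with identical panels and transform states.

    The merged table records per-event sample provenance.
    """
    if not tables:
        raise ValueError("merge_samples needs at least one table")
    first = tables[0]
    for t in tables[1:]:
        if t.channels != first.channels:
            raise ValueError(f"panel mismatch between {first.sample_id} and {t.sample_id}")
        if t.transform_state != first.transform_state:
            raise ValueError("transform state mismatch between tables")
    data = pd.concat([t.data for t in tables], ignore_index=True)
    provenance = np.concatenate(
        [np.repeat(t.sample_id, t.n_events) for t in tables]
    )
    truth = None
    if all(t.truth_labels is not None for t in tables):
        truth = np.concatenate([np.asarray(t.truth_labels) for t in tables])
    return EventTable(
        sample_id="+".join(t.sample_id for t in tables),
        data=data,
        transform_state=first.transform_state,
        transform_params=dict(first.transform_params),
        stained=first.stained,
        truth_labels=truth,
        provenance=provenance,
    )
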