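"""YAML config parsing for discovery queries and corpus plant specifications.

Query files carry the fields of :class:`~abclbd.discovery.DiscoveryQuery`
under the same names; plant files carry the fields of
:class:`~abclbd.synthetic.PlantSpec`, with ``pair_counts`` written as a list
of ``[cui_a, cui_b, count]`` triples.  Unknown keys are an error so typos
fail loudly.
"""

from __future__ import annotations

from pathlib import Path

import yaml

from .discovery import DiscoveryQuery
from .synthetic import PlantSpec

_QUERY_KEYS = {
    "a_term",
    "b_terms",
    "c_semantic_types",
    "min_ab_count",
    "min_bc_count",
    "keep_direct",
}

_PLANT_KEYS = {
    "pair_counts",
    "noise_vocab_size",
    "noise_documents",
    "noise_doc_length",
    "window_size",
    "seed",
}


def _load_mapping(path: str | Path) -> dict:
    with Path(path).open("r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config root must be a mapping")
    return data


def load_query(path: str | Path) -> DiscoveryQuery:
    """Read a discovery query from a YAML config file."""
    data = _load_mapping(path)
    unknown = set(data) - _QUERY_KEYS
    if unknown:
        raise ValueError(f"{path}: unknown query keys {sorted(unknown)}")
    if "a_term" not in data:
        raise ValueError(f"{path}: query config requires a_term")
    kwargs: dict = {"a_term": data["a_term"]}
    if data.get("b_terms") is not None:
        kwargs["b_restriction"] = frozenset(data["b_terms"])
    if data.get("c_semantic_types") is not None:
        kwargs["c_semantic_types"] = frozenset(data["c_semantic_types"])
    for key in ("min_ab_count", "min_bc_count", "keep_direct"):
        if key in data:
            kwargs[key] = data[key]
    return DiscoveryQuery(**kwargs)


def load_plant_spec(path: str | Path) -> PlantSpec:
    """Read a corpus plant specification from a YAML config file."""
    data = _load_mapping(path)
    unknown = set(data) - _PLANT_KEYS
    if unknown:
        raise ValueError(f"{path}: unknown plant keys {sorted(unknown)}")
    raw_pairs = data.get("pair_counts", [])
    pair_counts: dict[tuple[str, str], int] = {}
    for item in raw_pairs:
        if not (isinstance(item, (list, tuple)) and len(item) == 3):
            raise ValueError(
                f"{path}: pair_counts entries must be [cui_a, cui_b, count], got {item!r}"
            )
        a, b, count = item
        key = (a, b) if a < b else (b, a)
        if key in pair_counts:
            raise ValueError(f"{path}: pair ({a}, {b}) listed twice")
        pair_counts[key] = int(count)
    kwargs: dict = {"pair_counts": pair_counts}
    for key in _PLANT_KEYS - {"pair_counts"}:
        if key in data:
            kwargs[key] = int(data[key])
    return PlantSpec(**kwargs)
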