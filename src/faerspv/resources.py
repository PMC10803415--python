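"""Bundled default dictionaries and policy configs."""

from __future__ import annotations

from importlib import resources
from pathlib import Path
from typing import Union

import yaml

from .faers_io import read_pt_soc_map
from .preprocess import DrugDictionary, ExclusionPolicy, ExclusionEntry

_DATA = resources.files("faerspv") / "data"


def _data_path(name: str) -> Path:
    with resources.as_file(_DATA / name) as p:
        return Path(p)


def load_pt_soc_map(path: Union[str, Path, None] = None) -> dict[str, str]:
    """PT -> SOC mapping; the bundled toy dictionary when ``path`` is None."""
    return read_pt_soc_map(path if path is not None else _data_path("pt_soc_toy.tsv"))


def load_drug_config(path: Union[str, Path, None] = None) -> tuple[DrugDictionary, list[str]]:
    """Load a drug-dictionary YAML; returns (dictionary, role codes)."""
    p = path if path is not None else _data_path("drugs_default.yaml")
    cfg = yaml.safe_load(Path(p).read_text(encoding="utf-8"))
    dd = DrugDictionary({label: list(kw) for label, kw in cfg["drugs"].items()})
    roles = [str(r).upper() for r in cfg.get("roles", ["PS", "SS"])]
    return dd, roles


def default_drug_dictionary() -> DrugDictionary:
    return load_drug_config()[0]


def load_exclusion_policy(path: Union[str, Path, None] = None) -> ExclusionPolicy:
    p = path if path is not None else _data_path("exclusions_default.yaml")
    cfg = yaml.safe_load(Path(p).read_text(encoding="utf-8"))
    entries = [
        ExclusionEntry(term=e["term"], match=e.get("match", "exact"), reason=e.get("reason", "excluded"))
        for e in cfg.get("pt_terms", [])
    ]
    return ExclusionPolicy(
        pt_terms=entries,
        excluded_socs=list(cfg.get("socs", []) or []),
        injection_terms=[str(t) for t in cfg.get("injection_terms", []) or []],
    )


def default_exclusion_policy() -> ExclusionPolicy:
    return load_exclusion_policy()
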