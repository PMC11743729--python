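"""Readers and writers for rule bases (JSON) and feature datasets (CSV).

Rule-base documents are schema-versioned JSON with sections ``attributes``,
``attribute_weights``, ``grade_labels``, ``grade_utilities`` and ``rules``;
rule antecedents are serialized by semantic label (``["S", "N", "H"]``) so a
document reads against the published expert tables.  Loading validates every
rule-base invariant and rejects unknown fields; saving is canonical, so
save -> load -> save is byte-identical.

Two fixtures ship with the package: the initial expert-elicited 27-rule base
for the upper-limb model, and the reference trained parameters used as the
default ground-truth generator model.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .core import AttributeSpec, BeliefRuleBase, Rule, BELIEF_SUM_TOL

__all__ = [
    "SCHEMA_VERSION",
    "RuleBaseFormatError",
    "DatasetFormatError",
    "load_rulebase",
    "save_rulebase",
    "rulebase_to_document",
    "rulebase_from_document",
    "read_dataset",
    "write_dataset",
    "initial_expert_rulebase",
    "reference_trained_rulebase",
]

SCHEMA_VERSION = 1

_TOP_LEVEL_KEYS = {
    "schema_version",
    "provenance",
    "attributes",
    "attribute_weights",
    "grade_labels",
    "grade_utilities",
    "rules",
}
_ATTR_KEYS = {"name", "labels", "ref_values"}
_RULE_KEYS = {"antecedent", "theta", "beliefs"}


class RuleBaseFormatError(ValueError):
    """A rule-base document violates the schema or a model invariant."""


class DatasetFormatError(ValueError):
    """A dataset file violates the expected CSV layout."""


def rulebase_from_document(doc: dict) -> BeliefRuleBase:
    """Build a validated :class:`BeliefRuleBase` from a parsed JSON document."""
    if not isinstance(doc, dict):
        raise RuleBaseFormatError("rule-base document must be a JSON object")
    unknown = set(doc) - _TOP_LEVEL_KEYS
    if unknown:
        raise RuleBaseFormatError(f"unknown top-level fields: {sorted(unknown)}")
    missing = _TOP_LEVEL_KEYS - {"provenance"} - set(doc)
    if missing:
        raise RuleBaseFormatError(f"missing required fields: {sorted(missing)}")
    if doc["schema_version"] != SCHEMA_VERSION:
        raise RuleBaseFormatError(
            f"unsupported schema_version {doc['schema_version']!r} (expected {SCHEMA_VERSION})"
        )

    attributes = []
    for pos, a in enumerate(doc["attributes"], start=1):
        unknown = set(a) - _ATTR_KEYS
        if unknown:
            raise RuleBaseFormatError(f"attribute {pos}: unknown fields {sorted(unknown)}")
        try:
            attributes.append(
                AttributeSpec(name=a["name"], labels=a["labels"], ref_values=a["ref_values"])
            )
        except (KeyError, ValueError) as exc:
            raise RuleBaseFormatError(f"attribute {pos}: {exc}") from exc

    label_index = [{lab: j for j, lab in enumerate(a.labels)} for a in attributes]
    rules = []
    for pos, r in enumerate(doc["rules"], start=1):
        unknown = set(r) - _RULE_KEYS
        if unknown:
            raise RuleBaseFormatError(f"rule {pos}: unknown fields {sorted(unknown)}")
        ant_labels = r.get("antecedent")
        if not isinstance(ant_labels, list) or len(ant_labels) != len(attributes):
            raise RuleBaseFormatError(
                f"rule {pos}: antecedent must list one label per attribute "
                f"({len(attributes)} expected)"
            )
        antecedent = []
        for i, lab in enumerate(ant_labels):
            if lab not in label_index[i]:
                raise RuleBaseFormatError(
                    f"rule {pos}: label {lab!r} not among attribute "
                    f"{attributes[i].name!r} labels {list(attributes[i].labels)}"
                )
            antecedent.append(label_index[i][lab])
        beliefs = np.asarray(r.get("beliefs", []), dtype=float)
        total = float(beliefs.sum())
        if total > 1 + BELIEF_SUM_TOL:
            raise RuleBaseFormatError(
                f"rule {pos} ({', '.join(ant_labels)}): belief degrees sum to "
                f"{total:.12g} > 1"
            )
        try:
            rules.append(Rule(antecedent=tuple(antecedent), weight=float(r["theta"]), belief=beliefs))
        except (KeyError, ValueError) as exc:
            raise RuleBaseFormatError(f"rule {pos}: {exc}") from exc

    try:
        return BeliefRuleBase(
            attributes=tuple(attributes),
            attribute_weights=np.asarray(doc["attribute_weights"], dtype=float),
            rules=tuple(rules),
            grade_labels=tuple(doc["grade_labels"]),
            grade_utilities=np.asarray(doc["grade_utilities"], dtype=float),
        )
    except ValueError as exc:
        raise RuleBaseFormatError(str(exc)) from exc


def rulebase_to_document(brb: BeliefRuleBase, *, provenance: str | None = None) -> dict:
    """Serialize a rule base to its canonical document form (full precision)."""
    doc: dict = {"schema_version": SCHEMA_VERSION}
    if provenance is not None:
        doc["provenance"] = provenance
    doc["attributes"] = [
        {"name": a.name, "labels": list(a.labels), "ref_values": list(a.ref_values)}
        for a in brb.attributes
    ]
    doc["attribute_weights"] = [float(v) for v in brb.attribute_weights]
    doc["grade_labels"] = list(brb.grade_labels)
    doc["grade_utilities"] = [float(v) for v in brb.grade_utilities]
    doc["rules"] = [
        {
            "antecedent": [brb.attributes[i].labels[j] for i, j in enumerate(r.antecedent)],
            "theta": float(r.weight),
            "beliefs": [float(b) for b in r.belief],
        }
        for r in brb.rules
    ]
    return doc


def load_rulebase(path: str | Path) -> BeliefRuleBase:
    """Load and validate a rule base from a JSON file."""
    with open(path) as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise RuleBaseFormatError(f"{path}: not valid JSON ({exc})") from exc
    return rulebase_from_document(doc)


def save_rulebase(brb: BeliefRuleBase, path: str | Path, *, provenance: str | None = None) -> None:
    """Write a rule base as canonical JSON (round-trips exactly)."""
    doc = rulebase_to_document(brb, provenance=provenance)
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2)
        fh.write("\n")


# ---------------------------------------------------------------------------
# Packaged fixtures
# ---------------------------------------------------------------------------


def _load_fixture(name: str) -> BeliefRuleBase:
    text = resources.files("brb_rehab.fixtures").joinpath(f"{name}.json").read_text()
    return rulebase_from_document(json.loads(text))


def initial_expert_rulebase() -> BeliefRuleBase:
    """The published initial expert rule base: 27 rules, theta = delta = 1.

    Referential values: ARTUL {S: 4, N: 8, B: 12}, RTT {S: 5, N: 10, L: 15},
    MAMS {S: 5, N: 8, H: 11}; grades I-IV with utilities {1, 2, 3, 4}.
    """
    return _load_fixture("expert_initial")


def reference_trained_rulebase() -> BeliefRuleBase:
    """The published trained rule-base parameters (default truth model)."""
    return _load_fixture("trained_reference")


# ---------------------------------------------------------------------------
# Datasets
# ---------------------------------------------------------------------------

FEATURE_COLUMNS = ("artul", "rtt", "mams")
GRADE_COLUMN = "grade"


def read_dataset(path: str | Path, *, n_grades: int = 4):
    """Read a feature CSV with header ``artul,rtt,mams[,grade]``.

    Returns a :class:`~brb_rehab.simulate.LabelledDataset`; the grade column
    is optional (absent means unlabelled assessment mode).  Malformed cells
    and out-of-range grades are reported with their row numbers.
    """
    from .simulate import LabelledDataset  # local import to avoid a cycle

    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in FEATURE_COLUMNS if c not in df.columns]
    if missing:
        raise DatasetFormatError(f"{path}: missing required columns {missing}")
    extra = [c for c in df.columns if c not in FEATURE_COLUMNS + (GRADE_COLUMN,)]
    if extra:
        raise DatasetFormatError(f"{path}: unexpected columns {extra}")
    feats = df.loc[:, list(FEATURE_COLUMNS)].apply(pd.to_numeric, errors="coerce")
    bad = feats.isna().any(axis=1)
    if bad.any():
        rows = [int(i) + 2 for i in feats.index[bad][:5]]  # +2: header + 1-based
        raise DatasetFormatError(f"{path}: non-numeric feature cells at file rows {rows}")
    grades = None
    if GRADE_COLUMN in df.columns:
        g = pd.to_numeric(df[GRADE_COLUMN], errors="coerce")
        bad = g.isna() | (g != g.round()) | (g < 1) | (g > n_grades)
        if bad.any():
            rows = [int(i) + 2 for i in g.index[bad][:5]]
            raise DatasetFormatError(
                f"{path}: invalid grades (must be integers in 1..{n_grades}) at file rows {rows}"
            )
        grades = g.to_numpy(dtype=int)
    return LabelledDataset(features=feats.to_numpy(dtype=float), grades=grades)


def write_dataset(data, path: str | Path) -> None:
    """Write a dataset as CSV with full-precision floats."""
    df = pd.DataFrame(data.features, columns=list(FEATURE_COLUMNS))
    if data.grades is not None:
        df[GRADE_COLUMN] = data.grades
    df.to_csv(path, index=False, float_format="%.17g")
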