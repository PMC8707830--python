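"""The two germination-associated metabolic modules and candidate annotation.

Two module fixtures ship with the package:

* **ornithine–asparagine–polyamine** (15 members): the nitrogen-flow
  module — ornithine, L-asparagine and Asn + 2hexoside (consumed during
  germination) plus twelve polyamine entities (putrescine, spermidine,
  agmatine and their derivatives; accumulated, with N-acetylspermine the
  accumulation-before-consumption exception);
* **shikimate–aromatic–flavonoid** (14 members): shikimic acid, tyrosine,
  phenylalanine, four tryptophan derivatives (tryptamine,
  N-benzoyltryptamine, N-feruloyltryptamine, kynurenine) and seven
  flavonoids, all accumulated except cyanidin 3,5-di-O-hexoside.

Module members that the source figures do not name legibly are stored as
explicitly flagged placeholder rows (``ambiguous=true``) rather than
guessed, so the fixture cardinalities hold without inventing identities.
Users can supply their own module tables in the same schema
(``name, expected_direction, ambiguous``).

Matching is exact after normalization (case, unicode dashes, spacing,
Greek letters); no fuzzy matching.
"""

from __future__ import annotations

import unicodedata
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .core_io import InputError

__all__ = [
    "ModuleFixture",
    "load_module_fixtures",
    "load_candidate_class_counts",
    "normalize_name",
    "annotate_modules",
    "module_direction_summary",
]

_FIXTURE_FILES = {
    "ornithine-asparagine-polyamine": (
        "module_ornithine_asparagine_polyamine.csv",
        15,
    ),
    "shikimate-aromatic-flavonoid": ("module_shikimate_aromatic_flavonoid.csv", 14),
}

_GREEK = {
    "α": "alpha",
    "β": "beta",
    "γ": "gamma",
    "δ": "delta",
    "ε": "epsilon",
    "ω": "omega",
}


def normalize_name(name: str) -> str:
    """Canonical matching key: NFKC, lowercase, dashes/spaces stripped,
    Greek letters spelled out."""
    s = unicodedata.normalize("NFKC", str(name)).lower()
    for greek, latin in _GREEK.items():
        s = s.replace(greek, latin)
    for dash in ("−", "–", "—", "-", "_"):
        s = s.replace(dash, "")
    return "".join(s.split())


@dataclass
class ModuleFixture:
    """One metabolic module: name plus member table.

    ``members`` columns: ``name`` (printed string, the key),
    ``expected_direction`` ∈ {accumulation, consumption, special},
    ``ambiguous`` (placeholder row for an unenumerable printed name), and
    the derived ``normalized`` key.
    """

    name: str
    members: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"name", "expected_direction", "ambiguous"}
        if not required <= set(self.members.columns):
            raise InputError(f"module table needs columns {sorted(required)}")
        bad = set(self.members["expected_direction"]) - {
            "accumulation",
            "consumption",
            "special",
        }
        if bad:
            raise InputError(f"unknown expected_direction values: {sorted(bad)}")
        self.members = self.members.copy()
        self.members["normalized"] = self.members["name"].map(normalize_name)
        if self.members["normalized"].duplicated().any():
            dup = self.members.loc[self.members["normalized"].duplicated(), "name"].iloc[0]
            raise InputError(f"module {self.name!r}: duplicate member {dup!r}")

    def __len__(self) -> int:
        return len(self.members)


def load_module_fixtures() -> dict:
    """Load the bundled module fixtures, asserting their cardinalities."""
    out = {}
    for mod_name, (fname, expected_n) in _FIXTURE_FILES.items():
        with resources.files("germscreen.data").joinpath(fname).open() as fh:
            table = pd.read_csv(fh)
        fixture = ModuleFixture(name=mod_name, members=table)
        if len(fixture) != expected_n:
            raise InputError(
                f"module fixture {mod_name!r} has {len(fixture)} members, "
                f"expected {expected_n}"
            )
        out[mod_name] = fixture
    return out


def load_candidate_class_counts() -> pd.Series:
    """Bundled per-compound-class breakdown of the 74-candidate reference set."""
    with resources.files("germscreen.data").joinpath("candidate_class_counts.csv").open() as fh:
        df = pd.read_csv(fh)
    return df.set_index("compound_class")["count"]


def annotate_modules(
    candidates: Iterable[str],
    fixtures: Mapping[str, ModuleFixture] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Tag each candidate name with its module (or none).

    Matching is exact after :func:`normalize_name`.  A candidate matching
    entries in two different fixtures (or two entries of one fixture) is
    an error.  Returns ``(annotated table, unmatched fixture members)``;
    the second frame lists every fixture member no candidate matched,
    which is the full member list for an empty candidate set.
    """
    if fixtures is None:
        fixtures = load_module_fixtures()
    lookup: dict[str, tuple[str, str, str]] = {}
    for fixture in fixtures.values():
        for _, row in fixture.members.iterrows():
            key = row["normalized"]
            if key in lookup:
                raise InputError(
                    f"fixture member {row['name']!r} collides with "
                    f"{lookup[key][1]!r} in module {lookup[key][0]!r}"
                )
            lookup[key] = (fixture.name, row["name"], row["expected_direction"])
    rows = []
    matched_keys = set()
    for cand in candidates:
        key = normalize_name(cand)
        hit = lookup.get(key)
        if hit is not None:
            matched_keys.add(key)
        rows.append(
            {
                "candidate": cand,
                "module": hit[0] if hit else "none",
                "fixture_name": hit[1] if hit else "",
                "expected_direction": hit[2] if hit else "",
            }
        )
    annotated = pd.DataFrame(
        rows, columns=["candidate", "module", "fixture_name", "expected_direction"]
    )
    if annotated["candidate"].map(normalize_name).duplicated().any():
        dup = annotated.loc[
            annotated["candidate"].map(normalize_name).duplicated(), "candidate"
        ].iloc[0]
        raise InputError(f"ambiguous candidate list: {dup!r} appears more than once")
    unmatched = pd.concat(
        [
            fixture.members.loc[
                ~fixture.members["normalized"].isin(matched_keys),
                ["name", "expected_direction", "ambiguous"],
            ].assign(module=fixture.name)
            for fixture in fixtures.values()
        ],
        ignore_index=True,
    )
    return annotated, unmatched


def module_direction_summary(
    annotated: pd.DataFrame,
    patterns: pd.DataFrame,
    name_of: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Per-module counts of members whose observed pattern matches expectation.

    ``annotated`` comes from :func:`annotate_modules` (candidate column
    holding metabolite ids or names); ``patterns`` from
    :func:`~germscreen.patterns.trajectory_patterns`, with ``name_of``
    optionally mapping metabolite ids to printed names.  A member counts
    as consistent when every variety's observed label equals the expected
    direction, inconsistent otherwise; ``special``-direction members and
    members absent from the pattern table are reported as unevaluated.
    """
    pat = patterns.copy()
    key_col = "metabolite_id"
    if name_of is not None:
        pat["candidate_key"] = pat[key_col].map(lambda m: normalize_name(name_of.get(m, m)))
    else:
        pat["candidate_key"] = pat[key_col].map(normalize_name)
    labels_by_key = pat.groupby("candidate_key")["label"].apply(list)
    rows = []
    members = annotated[annotated["module"] != "none"]
    for module, grp in members.groupby("module"):
        consistent = inconsistent = unevaluated = 0
        for _, row in grp.iterrows():
            key = normalize_name(row["candidate"])
            expected = row["expected_direction"]
            if expected == "special" or key not in labels_by_key.index:
                unevaluated += 1
            elif all(lbl == expected for lbl in labels_by_key[key]):
                consistent += 1
            else:
                inconsistent += 1
        evaluated = consistent + inconsistent
        rows.append(
            {
                "module": module,
                "n_members": len(grp),
                "consistent": consistent,
                "inconsistent": inconsistent,
                "unevaluated": unevaluated,
                "consistency": consistent / evaluated if evaluated else float("nan"),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "module",
            "n_members",
            "consistent",
            "inconsistent",
            "unevaluated",
            "consistency",
        ],
    )
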