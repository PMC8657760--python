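"""Instrument blueprint: domains, facets, items, keying and antonym pairing.

The default blueprint describes a balanced social-emotional skills inventory:
five broad domains (a social-emotional Big Five), 18 facets, and nine items
per facet — three positively keyed identity items, three negatively keyed
identity items (together forming three antonym pairs), and three positively
keyed self-efficacy items, for 162 items in total.

Every downstream stage (acquiescence estimation, cluster scoring, factor
target construction) indexes against this blueprint, so it is validated
strictly: keying must match framing, antonym pairs must be complete and
facet-consistent, and facet composition must be exactly 3 + 3 + 3.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

FRAMINGS = ("identity_neg", "identity_pos", "self_efficacy")

#: Domain codes in canonical order.
DOMAIN_ORDER = ("O", "C", "E", "A", "N")

_DEFAULT_DOMAINS = {
    "O": "Open-mindedness",
    "C": "Self-management",
    "E": "Engaging with others",
    "A": "Amity",
    "N": "Negative-emotion regulation",
}

# Facets per domain, in the canonical order used by the published loading
# tables (domain blocks O, C, E, A, N; facet order within block as printed).
_DEFAULT_FACETS = [
    ("artistic_interest", "O"),
    ("creative_imagination", "O"),
    ("curiosity_to_learn", "O"),
    ("determination", "C"),
    ("focus", "C"),
    ("organization", "C"),
    ("persistence", "C"),
    ("responsibility", "C"),
    ("enthusiasm", "E"),
    ("assertiveness", "E"),
    ("social_initiative", "E"),
    ("empathy", "A"),
    ("gratitude", "A"),
    ("respect", "A"),
    ("trust", "A"),
    ("frustration_tolerance", "N"),
    ("stress_modulation", "N"),
    ("self_confidence", "N"),
]


class BlueprintError(ValueError):
    """Raised when a blueprint or item-key table violates design invariants."""

    def __init__(self, problems):
        if isinstance(problems, str):
            problems = [problems]
        self.problems = list(problems)
        super().__init__("; ".join(self.problems))


@dataclass(frozen=True)
class DomainSpec:
    code: str
    label: str


@dataclass(frozen=True)
class FacetSpec:
    facet_id: str
    domain: str


@dataclass(frozen=True)
class ItemSpec:
    item_id: str
    facet: str
    framing: str  # identity_pos | identity_neg | self_efficacy
    key: int  # +1 or -1; -1 iff identity_neg
    pair_id: str | None = None  # antonym-pair token; None for self_efficacy


@dataclass(frozen=True)
class InstrumentBlueprint:
    """Validated instrument design. Items are stored in canonical order
    (domain, facet, framing) so loading tables are comparable across runs."""

    domains: tuple[DomainSpec, ...]
    facets: tuple[FacetSpec, ...]
    items: tuple[ItemSpec, ...]

    def __post_init__(self):
        problems = _validate(self.domains, self.facets, self.items)
        if problems:
            raise BlueprintError(problems)

    # -- convenience lookups ------------------------------------------------
    @property
    def domain_codes(self) -> tuple[str, ...]:
        return tuple(d.code for d in self.domains)

    @property
    def item_ids(self) -> tuple[str, ...]:
        return tuple(it.item_id for it in self.items)

    @property
    def identity_item_ids(self) -> tuple[str, ...]:
        return tuple(
            it.item_id for it in self.items if it.framing != "self_efficacy"
        )

    def facet_domain(self, facet_id: str) -> str:
        for f in self.facets:
            if f.facet_id == facet_id:
                return f.domain
        raise KeyError(facet_id)

    def item(self, item_id: str) -> ItemSpec:
        for it in self.items:
            if it.item_id == item_id:
                return it
        raise KeyError(item_id)

    def keys(self) -> pd.Series:
        """Item key signs (+1/-1) indexed by item_id, in blueprint order."""
        return pd.Series(
            {it.item_id: it.key for it in self.items}, name="key"
        ).reindex(list(self.item_ids))

    def to_frame(self) -> pd.DataFrame:
        """Serialize to the item-key table (one row per item)."""
        rows = []
        for it in self.items:
            rows.append(
                {
                    "item_id": it.item_id,
                    "domain": self.facet_domain(it.facet),
                    "facet": it.facet,
                    "framing": it.framing,
                    "key": it.key,
                    "pair_id": it.pair_id or "",
                }
            )
        return pd.DataFrame(rows)


def _validate(domains, facets, items) -> list[str]:
    problems: list[str] = []
    codes = [d.code for d in domains]
    if len(set(codes)) != len(codes):
        problems.append("duplicate domain codes")
    code_set = set(codes)

    facet_ids = [f.facet_id for f in facets]
    if len(set(facet_ids)) != len(facet_ids):
        problems.append("duplicate facet ids")
    facet_domain = {f.facet_id: f.domain for f in facets}
    for f in facets:
        if f.domain not in code_set:
            problems.append(f"facet {f.facet_id!r} references unknown domain {f.domain!r}")

    ids = [it.item_id for it in items]
    dup = {i for i in ids if ids.count(i) > 1}
    if dup:
        problems.append(f"duplicate item_id(s): {sorted(dup)}")

    per_facet: dict[str, dict[str, int]] = {}
    pair_members: dict[str, list[ItemSpec]] = {}
    for it in items:
        if it.facet not in facet_domain:
            problems.append(f"item {it.item_id!r} references unknown facet {it.facet!r}")
            continue
        if it.framing not in FRAMINGS:
            problems.append(f"item {it.item_id!r} has unknown framing {it.framing!r}")
            continue
        expected_key = -1 if it.framing == "identity_neg" else 1
        if it.key != expected_key:
            problems.append(
                f"item {it.item_id!r}: key {it.key:+d} inconsistent with framing {it.framing}"
            )
        if it.framing == "self_efficacy":
            if it.pair_id:
                problems.append(f"self_efficacy item {it.item_id!r} must not carry a pair_id")
        else:
            if not it.pair_id:
                problems.append(f"identity item {it.item_id!r} is missing a pair_id")
            else:
                pair_members.setdefault(it.pair_id, []).append(it)
        per_facet.setdefault(it.facet, {fr: 0 for fr in FRAMINGS})[it.framing] += 1

    for facet_id, counts in per_facet.items():
        for fr in FRAMINGS:
            if counts[fr] != 3:
                problems.append(
                    f"facet {facet_id!r}: {counts[fr]} {fr} items (expected 3)"
                )
    missing_facets = set(facet_domain) - set(per_facet)
    for facet_id in sorted(missing_facets):
        problems.append(f"facet {facet_id!r} has no items")

    for pair_id, members in pair_members.items():
        framings = sorted(m.framing for m in members)
        if framings != ["identity_neg", "identity_pos"]:
            problems.append(
                f"pair {pair_id!r} must contain exactly one identity_pos and one "
                f"identity_neg item (got {framings})"
            )
        elif members[0].facet != members[1].facet:
            problems.append(f"pair {pair_id!r} spans facets "
                            f"{members[0].facet!r} and {members[1].facet!r}")
    return problems


def build_default_blueprint() -> InstrumentBlueprint:
    """The canonical 5-domain / 18-facet / 162-item balanced design.

    Item ids are synthetic tokens, e.g. ``empathy_idpos_1``; pair ``k`` links
    ``<facet>_idpos_k`` with ``<facet>_idneg_k``.
    """
    return build_blueprint(_DEFAULT_DOMAINS, _DEFAULT_FACETS)


def build_blueprint(
    domains: dict[str, str], facets: Sequence[tuple[str, str]]
) -> InstrumentBlueprint:
    """Build a balanced 3+3+3-per-facet blueprint from a domain map and an
    ordered (facet_id, domain_code) sequence."""
    domain_specs = tuple(
        DomainSpec(code, label)
        for code, label in domains.items()
    )
    facet_specs = tuple(FacetSpec(fid, dom) for fid, dom in facets)
    items: list[ItemSpec] = []
    order = {c: i for i, c in enumerate(domains)}
    for fid, dom in sorted(facets, key=lambda t: (order[t[1]], _facet_rank(facets, t[0]))):
        for framing, short in (("identity_neg", "idneg"), ("identity_pos", "idpos"),
                               ("self_efficacy", "se")):
            for k in (1, 2, 3):
                pair = f"{fid}_pair{k}" if framing != "self_efficacy" else None
                items.append(
                    ItemSpec(
                        item_id=f"{fid}_{short}_{k}",
                        facet=fid,
                        framing=framing,
                        key=-1 if framing == "identity_neg" else 1,
                        pair_id=pair,
                    )
                )
    return InstrumentBlueprint(domain_specs, facet_specs, tuple(items))


def _facet_rank(facets, fid):
    for i, (f, _) in enumerate(facets):
        if f == fid:
            return i
    return len(facets)


def antonym_pairs(bp: InstrumentBlueprint) -> list[tuple[ItemSpec, ItemSpec]]:
    """All (identity_pos, identity_neg) antonym pairs, in blueprint order.

    The pairing is a bijection between positively and negatively keyed
    identity items; a dangling or mixed-facet pair raises BlueprintError.
    (The blueprint constructor enforces the same invariants, so for an
    InstrumentBlueprint instance this cannot fail; the check covers
    duck-typed inputs.)
    """
    members: dict[str, dict[str, ItemSpec]] = {}
    for it in bp.items:
        if it.framing in ("identity_pos", "identity_neg") and it.pair_id:
            members.setdefault(it.pair_id, {})[it.framing] = it
    problems = []
    pairs = []
    seen = set()
    for it in bp.items:
        if it.framing != "identity_pos" or not it.pair_id or it.pair_id in seen:
            continue
        seen.add(it.pair_id)
        entry = members.get(it.pair_id, {})
        neg = entry.get("identity_neg")
        if neg is None:
            problems.append(f"pair {it.pair_id!r} has no identity_neg member")
            continue
        if neg.facet != it.facet:
            problems.append(f"pair {it.pair_id!r} spans facets")
            continue
        pairs.append((it, neg))
    orphan_neg = {
        it.pair_id for it in bp.items
        if it.framing == "identity_neg" and it.pair_id not in seen
    }
    for pid in sorted(p for p in orphan_neg if p):
        problems.append(f"pair {pid!r} has no identity_pos member")
    if problems:
        raise BlueprintError(problems)
    return pairs


def validate_itemkey(table) -> InstrumentBlueprint:
    """Validate an item-key table and return the blueprint it encodes.

    ``table`` is a DataFrame, a path to a CSV, or an iterable of records with
    fields item_id, domain, facet, framing, key, pair_id. All violations are
    collected and reported together.
    """
    if isinstance(table, (str, Path, io.IOBase)):
        df = pd.read_csv(table, dtype=str, keep_default_na=False)
    elif isinstance(table, pd.DataFrame):
        df = table.astype(str)
    else:
        df = pd.DataFrame(list(table)).astype(str)
    required = {"item_id", "domain", "facet", "framing", "key", "pair_id"}
    missing = required - set(df.columns)
    if missing:
        raise BlueprintError(f"item-key table missing column(s): {sorted(missing)}")

    domains: dict[str, str] = {}
    facets: list[tuple[str, str]] = []
    items: list[ItemSpec] = []
    problems: list[str] = []
    for rec in df.to_dict("records"):
        dom = rec["domain"].strip()
        fid = rec["facet"].strip()
        domains.setdefault(dom, dom)
        if fid not in [f for f, _ in facets]:
            facets.append((fid, dom))
        elif dict(facets)[fid] != dom:
            problems.append(f"facet {fid!r} mapped to multiple domains")
        try:
            key = int(rec["key"])
        except ValueError:
            problems.append(f"item {rec['item_id']!r}: non-integer key {rec['key']!r}")
            key = 0
        items.append(
            ItemSpec(
                item_id=rec["item_id"].strip(),
                facet=fid,
                framing=rec["framing"].strip(),
                key=key,
                pair_id=rec["pair_id"].strip() or None,
            )
        )
    if problems:
        raise BlueprintError(problems)
    domain_specs = tuple(
        DomainSpec(c, _DEFAULT_DOMAINS.get(c, c)) for c in domains
    )
    return InstrumentBlueprint(domain_specs, tuple(FacetSpec(f, d) for f, d in facets),
                               tuple(items))


def default_itemkey_path() -> Path:
    """Path to the packaged item-key CSV for the default blueprint."""
    return Path(__file__).parent / "data" / "item_key.csv"


def write_itemkey(bp: InstrumentBlueprint, path) -> None:
    bp.to_frame().to_csv(path, index=False)
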