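"""Deterministic URI construction.

Every node created during a build — field values, records, identifier sets,
OWL restrictions, generated biomedical classes — receives a URI whose token is
the URL-safe base64 encoding of the SHA-1 digest of a documented byte
serialization. Identical inputs always produce identical URIs, so two builds
from the same sources mint the same graph and shared structure (field values,
restrictions) is reused without any lookup table. Blank nodes are never used.

Payload serialization convention: UTF-8 bytes of ``"<kind-tag>|"`` followed by
the pipe-joined components of the entity. Distinct kinds carry distinct tags,
so cross-kind collisions are impossible even for identical components.
"""

from __future__ import annotations

import base64
import hashlib
import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Optional, Sequence

import yaml
from rdflib import URIRef

from .namespaces import KBIO, KIAO

# Kind tags; see docs/methods.md for the full recipe table.
KIND_FIELD_VALUE = "fv"
KIND_RECORD = "rec"
KIND_ID_SET = "ids"
KIND_RESTRICTION = "rst"
KIND_BIO_CLASS = "bio"


class EmptySet(ValueError):
    """Raised when a set URI is requested for zero members."""


class UnknownDialect(ValueError):
    """Raised when no identifier dialect rule matches a raw value."""


def sha1_b64url(payload: bytes) -> str:
    """URL-safe base64 token (padding stripped) of the SHA-1 digest.

    Pure function; the token is always 27 characters drawn from
    ``A–Z a–z 0–9 - _``.
    """
    digest = hashlib.sha1(payload).digest()
    return base64.urlsafe_b64encode(digest).rstrip(b"=").decode("ascii")


def _payload(kind: str, components: Sequence[str]) -> bytes:
    # Components are URIs or identifier strings; the delimiter (and the escape
    # character itself) must be escaped or the serialization is ambiguous.
    escaped = [c.replace("%", "%25").replace("|", "%7C") for c in components]
    return (kind + "|" + "|".join(escaped)).encode("utf-8")


def mint_token(kind: str, components: Sequence[str]) -> str:
    return sha1_b64url(_payload(kind, components))


def mint_field_value_uri(schema_label: str, field_name: str, value: str) -> URIRef:
    token = mint_token(KIND_FIELD_VALUE, [schema_label, field_name, value])
    return URIRef(f"{KIAO}F_{schema_label}_{field_name}_{token}")


def mint_record_uri(schema_uri: str, key: str) -> URIRef:
    token = mint_token(KIND_RECORD, [schema_uri, key])
    return URIRef(f"{KIAO}R_{token}")


def mint_set_uri(members: Iterable[str]) -> URIRef:
    """Permutation-invariant identifier-set URI.

    Members are lexicographically sorted by URI string before serialization,
    so any input ordering yields the same URI; distinct member sets yield
    distinct URIs (up to hash collision).
    """
    sorted_members = sorted({str(m) for m in members})
    if not sorted_members:
        raise EmptySet("identifier set must have at least one member")
    token = mint_token(KIND_ID_SET, sorted_members)
    return URIRef(f"{KIAO}ID-Set-{token}")


def mint_restriction_uri(prop: str, filler: str) -> URIRef:
    """URI for an all-some restriction, a pure function of (property, filler).

    Reused wherever the same restriction is needed, which keeps the
    restriction-node count equal to the number of distinct
    (owl:onProperty, owl:someValuesFrom) pairs graph-wide.
    """
    token = mint_token(KIND_RESTRICTION, [str(prop), str(filler)])
    return URIRef(f"{KBIO}R_{token}")


def mint_bio_class_uri(tag: str, components: Sequence[str], *, uri_prefix: str = "BIO_") -> URIRef:
    """URI for a generated biomedical class.

    ``tag`` names the generating pattern (e.g. ``set``, ``gorgp``, ``goa``,
    ``int``) so classes produced by different rules never collide.
    """
    token = mint_token(KIND_BIO_CLASS, [tag, *[str(c) for c in components]])
    return URIRef(f"{KBIO}{uri_prefix}{token}")


# ---------------------------------------------------------------------------
# Identifier canonicalization


@dataclass(frozen=True)
class FieldContext:
    """Where a raw identifier string was observed.

    ``identifier_source`` names the dialect whose bare lexical forms the field
    is designated to contain (e.g. a gene-id column may hold bare numerals).
    """

    schema_label: str = ""
    field_name: str = ""
    identifier_source: Optional[str] = None


ANY_CONTEXT = FieldContext()


@dataclass(frozen=True)
class IdentifierDialectRule:
    """Lexical dialects of one identifier space.

    ``patterns`` are full-match regexes with a ``local`` group and apply in any
    context; ``bare_patterns`` apply only when the field context designates
    this source (a bare "513" means an NCBI-gene-style id only inside a field
    declared to contain such ids).
    """

    source: str
    canonical_prefix: str
    patterns: Sequence[str]
    bare_patterns: Sequence[str] = ()

    def match_local(self, raw: str, *, bare_ok: bool) -> Optional[str]:
        pats = list(self.patterns) + (list(self.bare_patterns) if bare_ok else [])
        for pat in pats:
            m = re.fullmatch(pat, raw)
            if m:
                return m.group("local")
        return None


_ICE_URI_RE = re.compile(re.escape(str(KIAO)) + r"(?P<prefix>[A-Za-z0-9]+)_(?P<local>[^/]+)_ICE$")


@dataclass
class DialectTable:
    """All dialect rules for one build, loaded from a declarative config."""

    rules: Sequence[IdentifierDialectRule] = field(default_factory=list)

    @classmethod
    def from_config(cls, mapping: Mapping) -> "DialectTable":
        rules = [
            IdentifierDialectRule(
                source=entry["source"],
                canonical_prefix=entry.get("canonical_prefix", entry["source"]),
                patterns=tuple(entry.get("patterns", ())),
                bare_patterns=tuple(entry.get("bare_patterns", ())),
            )
            for entry in mapping["dialects"]
        ]
        return cls(rules)

    @classmethod
    def builtin(cls) -> "DialectTable":
        text = resources.files("icebio.data").joinpath("dialects.yaml").read_text()
        return cls.from_config(yaml.safe_load(text))

    def canonical_uri(self, source: str, local: str) -> URIRef:
        rule = next(r for r in self.rules if r.source == source)
        return URIRef(f"{KIAO}{rule.canonical_prefix}_{local}_ICE")

    def canonicalize(self, raw: str, context: FieldContext = ANY_CONTEXT) -> URIRef:
        """One canonical ICE URI per underlying identifier.

        Idempotent: an already-canonical URI (or its ``PREFIX_local_ICE``
        suffix form) maps to itself. Raises :class:`UnknownDialect` when no
        rule matches; callers quarantine the record and continue the build.
        """
        raw = raw.strip()
        if not raw:
            raise UnknownDialect("empty identifier")
        m = _ICE_URI_RE.match(raw)
        if m:
            return URIRef(raw)
        for rule in self.rules:
            bare_ok = context.identifier_source == rule.source
            local = rule.match_local(raw, bare_ok=bare_ok)
            if local is not None:
                return URIRef(f"{KIAO}{rule.canonical_prefix}_{local}_ICE")
        raise UnknownDialect(f"no dialect rule matches {raw!r} (context={context.field_name or 'any'})")

    def source_of(self, uri: str) -> Optional[str]:
        """Identifier space of a canonical ICE URI, or None."""
        m = _ICE_URI_RE.match(str(uri))
        if not m:
            return None
        for rule in self.rules:
            if rule.canonical_prefix == m.group("prefix"):
                return rule.source
        return None
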