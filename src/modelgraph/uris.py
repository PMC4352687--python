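"""Normalization of annotation resource URIs.

Model corpora mix two spellings of the same identifier: MIRIAM URNs
(``urn:miriam:obo.go:GO%3A0005892``) and identifiers.org URLs
(``http://identifiers.org/go/GO:0005892``).  Resource nodes are
deduplicated on a canonical ``(collection, accession)`` key so that both
spellings land on one node.
"""

from __future__ import annotations

from dataclasses import dataclass
from urllib.parse import unquote

# MIRIAM collection aliases folded onto one canonical tag.
_COLLECTION_ALIASES = {
    "biomodels.sbo": "sbo",
    "biomodels.kisao": "kisao",
    "obo.sbo": "sbo",
    "obo.kisao": "kisao",
    "obo.go": "go",
    "obo.chebi": "chebi",
    "obo.interpro": "interpro",
    "ec-code": "ec",
    "intenz": "ec",
}


@dataclass(frozen=True)
class ResourceKey:
    """Canonical identity of an external resource."""

    collection: str
    accession: str
    parsed: bool = True

    @property
    def key(self) -> str:
        return f"{self.collection}:{self.accession}"


def _canonical_collection(raw: str) -> str:
    coll = raw.strip().lower()
    return _COLLECTION_ALIASES.get(coll, coll)


def normalize_uri(uri: str) -> tuple[ResourceKey, str | None]:
    """Map a resource URI onto its canonical key.

    Returns ``(key, warning)``; an unparseable URI passes through
    verbatim (``parsed=False``) with a warning message instead of being
    dropped, so odd annotations stay queryable.
    """
    if not uri or not uri.strip():
        raise ValueError("empty resource URI")
    text = uri.strip()
    if text.lower().startswith("urn:miriam:"):
        rest = text[len("urn:miriam:"):]
        parts = rest.split(":", 1)
        if len(parts) == 2 and parts[0] and parts[1]:
            return ResourceKey(_canonical_collection(parts[0]), unquote(parts[1])), None
        return ResourceKey("", text, parsed=False), f"unparseable MIRIAM URN: {uri!r}"
    lowered = text.lower()
    for scheme in ("http://identifiers.org/", "https://identifiers.org/"):
        if lowered.startswith(scheme):
            rest = text[len(scheme):]
            parts = rest.split("/", 1)
            if len(parts) == 2 and parts[0] and parts[1]:
                return ResourceKey(_canonical_collection(parts[0]), unquote(parts[1])), None
            return ResourceKey("", text, parsed=False), f"unparseable identifiers.org URL: {uri!r}"
    return ResourceKey("", text, parsed=False), f"unrecognized resource URI scheme: {uri!r}"


def local_part(uri: str) -> str:
    """Human-readable tail of a URI, used to seed description text."""
    key, warning = normalize_uri(uri)
    if warning is None:
        return key.accession
    return unquote(uri.rstrip("/").rsplit("/", 1)[-1].rsplit(":", 1)[-1])
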