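"""Shorthand lipid nomenclature parsing.

Plasma lipidomics platforms report species under a compact shorthand:
a headgroup token (``PC``, ``LPE``, ``TG`` ...), an optional ether marker
(``(O-`` for alkyl / plasmanyl, ``(P-`` for alkenyl / plasmenyl bonds at
*sn-1*), fatty-chain tokens written ``carbons:double-bonds``, and optional
bracketed feature tags such as the acyl position (``[sn1]``, ``[sn2]``) or
the PUFA series (``[n-3]``, ``[n-6]``).  Chains separated by ``/`` have
known *sn* positions; ``_`` means the positions are unresolved.

Examples of accepted names::

    PC                      bare class
    PE(P)                   bare ether class (alkenyl)
    Total PE Ether          composite class: PE(O) + PE(P)
    PE(P-16:0/20:4)         alkenyl PE, sn1 16:0 / sn2 20:4
    PE(16:0_18:2)           diacyl PE, chain positions unresolved
    LPC(22:5) [sn2]         lyso PC, 22:5 acyl at sn-2
    SM(34:1)                sum-composition sphingolipid
    TG(16:0_18:1_18:2)      three chains

``parse_lipid_name`` -> ``LipidAnnotation`` -> ``render`` is a fixed point
for every name the package emits.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

__all__ = ["LipidAnnotation", "LipidNameError", "parse_lipid_name", "render"]

ACYL = "acyl"
ALKYL = "alkyl"
ALKENYL = "alkenyl"

_CHAIN_RE = re.compile(r"^\d+:\d+$")
_HEAD_RE = re.compile(r"^[A-Za-z][A-Za-z0-9]*")
_TAG_RE = re.compile(r"\[([^\]]+)\]")

# tags normalised on parse; render writes them back verbatim (feature_tags
# keep the original spelling so parse->render->parse is a fixed point)
_OMEGA_TAGS = {"n3": "n-3", "n-3": "n-3", "n6": "n-6", "n-6": "n-6"}


class LipidNameError(ValueError):
    """Raised for malformed shorthand lipid names."""


@dataclass(frozen=True)
class LipidAnnotation:
    """Structured annotation of one lipid species (or class token)."""

    species_name: str
    class_code: str
    linkage: str = ACYL  # acyl | alkyl | alkenyl
    sn1_chain: str | None = None
    sn2_chain: str | None = None
    sn3_chain: str | None = None
    sn_known: bool = True  # False when chains were '_'-separated
    omega_series: str | None = None  # "n-3" | "n-6" | None
    feature_tags: tuple[str, ...] = field(default_factory=tuple)

    @property
    def chains(self) -> tuple[str, ...]:
        return tuple(
            c for c in (self.sn1_chain, self.sn2_chain, self.sn3_chain) if c is not None
        )

    @property
    def is_class_token(self) -> bool:
        """True for bare class names like ``PC`` or ``Total PE Ether``."""
        return not self.chains


def _check_parens(name: str) -> None:
    depth = 0
    for ch in name:
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
        if depth < 0:
            raise LipidNameError(f"unbalanced parentheses in {name!r}")
    if depth != 0:
        raise LipidNameError(f"unbalanced parentheses in {name!r}")


def _check_chain(token: str, name: str) -> str:
    if not _CHAIN_RE.match(token):
        raise LipidNameError(f"non-numeric chain token {token!r} in {name!r}")
    return token


def parse_lipid_name(name: str) -> LipidAnnotation:
    """Parse a shorthand lipid name into a :class:`LipidAnnotation`.

    Raises :class:`LipidNameError` naming the offending token for malformed
    input (unbalanced parentheses, non-numeric chains, empty names).
    """
    if not name or not name.strip():
        raise LipidNameError("empty lipid name")
    original = name.strip()
    _check_parens(original)

    # composite class tokens, e.g. "Total PE Ether"
    if original.startswith("Total "):
        return LipidAnnotation(species_name=original, class_code=original, linkage=ACYL)

    # split off bracketed feature tags
    tags = tuple(t.strip() for t in _TAG_RE.findall(original))
    body = _TAG_RE.sub("", original).strip()
    omega = None
    for t in tags:
        if t in _OMEGA_TAGS:
            omega = _OMEGA_TAGS[t]

    m = _HEAD_RE.match(body)
    if not m:
        raise LipidNameError(f"cannot find headgroup token in {name!r}")
    head = m.group(0)
    rest = body[m.end():]

    linkage = ACYL
    ether = ""
    chains: list[str] = []
    sn_known = True

    if rest:
        if not (rest.startswith("(") and rest.endswith(")")):
            raise LipidNameError(f"unexpected trailing token {rest!r} in {name!r}")
        inner = rest[1:-1]
        if inner in ("O", "P"):
            ether = inner  # bare ether class, e.g. PE(P)
        else:
            if inner.startswith("O-"):
                ether, inner = "O", inner[2:]
            elif inner.startswith("P-"):
                ether, inner = "P", inner[2:]
            if "/" in inner and "_" in inner:
                raise LipidNameError(f"mixed chain separators in {name!r}")
            sep = "/" if "/" in inner else "_"
            sn_known = "/" in inner or ("_" not in inner)
            chains = [_check_chain(tok, original) for tok in inner.split(sep) if tok]
            if not chains:
                raise LipidNameError(f"empty chain list in {name!r}")
            if len(chains) > 3:
                raise LipidNameError(f"more than three chains in {name!r}")

    if ether == "P":
        linkage = ALKENYL
    elif ether == "O":
        linkage = ALKYL

    class_code = f"{head}({ether})" if ether else head

    sn1 = sn2 = sn3 = None
    if chains:
        if len(chains) == 1:
            # lyso / single-chain species: position from an [sn*] tag, default sn1
            if any(t in ("sn2", "sn-2") for t in tags):
                sn2 = chains[0]
            else:
                sn1 = chains[0]
        else:
            sn1 = chains[0]
            sn2 = chains[1]
            sn3 = chains[2] if len(chains) > 2 else None

    return LipidAnnotation(
        species_name=original,
        class_code=class_code,
        linkage=linkage,
        sn1_chain=sn1,
        sn2_chain=sn2,
        sn3_chain=sn3,
        sn_known=sn_known,
        omega_series=omega,
        feature_tags=tags,
    )


def render(ann: LipidAnnotation) -> str:
    """Render an annotation back to its shorthand string."""
    if ann.class_code.startswith("Total "):
        return ann.class_code
    m = re.match(r"^([A-Za-z][A-Za-z0-9]*)(?:\(([OP])\))?$", ann.class_code)
    if not m:
        raise LipidNameError(f"unrenderable class code {ann.class_code!r}")
    head, ether = m.group(1), m.group(2)
    chains = ann.chains
    body = head
    if chains:
        sep = "/" if ann.sn_known else "_"
        chain_str = sep.join(chains)
        if ether:
            body += f"({ether}-{chain_str})"
        else:
            body += f"({chain_str})"
    elif ether:
        body += f"({ether})"
    if ann.feature_tags:
        body += " " + " ".join(f"[{t}]" for t in ann.feature_tags)
    return body
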