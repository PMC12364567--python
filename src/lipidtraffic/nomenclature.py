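"""Shorthand lipid nomenclature: parsing, formatting and compact-list expansion.

Lipidomics platforms report species in a compact shorthand such as
``PC(34:2)`` (class, total acyl carbons : total double bonds),
``TG(17:0/17:0/17:0)`` (sn-resolved chains) or ``PC-O(33:2)`` (ether
variant).  This module turns those strings into structured
:class:`LipidName` values so downstream stages can group variables by
class and chain properties, and formats them back canonically so that
``parse(format(x)) == x`` holds.

Only compositional identity is modelled: no sn-position beyond the
printed chain order, no double-bond location, no mass computation.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import Iterable

__all__ = [
    "LipidName",
    "LipidNameError",
    "UnknownLipidClassWarning",
    "KNOWN_CLASSES",
    "parse_lipid_name",
    "format_lipid_name",
    "expand_compact_list",
    "lipid_class",
]

#: Class codes recognised without warning.  Vendor exports may carry other
#: codes; those parse fine but raise :class:`UnknownLipidClassWarning`.
KNOWN_CLASSES = frozenset(
    {
        "PC", "PE", "PI", "PS", "PA", "PG",
        "LPC", "LPE", "LPI", "LPS", "LPA",
        "SM", "Cer", "HexCer", "CE", "DG", "MG", "TG", "FA", "CL",
    }
)


class LipidNameError(ValueError):
    """Raised when a shorthand lipid name cannot be parsed."""


class UnknownLipidClassWarning(UserWarning):
    """Emitted when a name parses structurally but its class code is unknown."""


@dataclass(frozen=True)
class LipidName:
    """Parsed shorthand lipid identity.

    Parameters
    ----------
    class_code:
        Lipid class token, e.g. ``"PC"`` or ``"TG"``.
    ether_flag:
        True for the ``-O`` (ether / plasmanyl) variant.
    oxidized_flag:
        True for the ``ox`` / ``oxo`` variant.
    total_carbons, total_double_bonds:
        Summed acyl composition.
    chains:
        Optional tuple of ``(carbons, double_bonds)`` pairs when the name
        is sn-resolved; their sums must equal the totals.
    """

    class_code: str
    total_carbons: int
    total_double_bonds: int
    ether_flag: bool = False
    oxidized_flag: bool = False
    chains: tuple[tuple[int, int], ...] | None = field(default=None)

    def __post_init__(self) -> None:
        if not self.class_code:
            raise LipidNameError("empty class code")
        if self.total_carbons < 0 or self.total_double_bonds < 0:
            raise LipidNameError(
                f"negative composition in {self.class_code}"
                f"({self.total_carbons}:{self.total_double_bonds})"
            )
        if self.total_carbons < self.total_double_bonds:
            raise LipidNameError(
                f"more double bonds than carbons: "
                f"{self.class_code}({self.total_carbons}:{self.total_double_bonds})"
            )
        if self.chains is not None:
            c = sum(ch[0] for ch in self.chains)
            d = sum(ch[1] for ch in self.chains)
            if (c, d) != (self.total_carbons, self.total_double_bonds):
                raise LipidNameError(
                    f"chain sums ({c}:{d}) disagree with totals "
                    f"({self.total_carbons}:{self.total_double_bonds})"
                )
            for cc, dd in self.chains:
                if cc < 0 or dd < 0 or cc < dd:
                    raise LipidNameError(f"invalid chain ({cc}:{dd})")
            if len(self.chains) == 1:
                # a single chain is indistinguishable from the totals form
                object.__setattr__(self, "chains", None)

    @property
    def recognized(self) -> bool:
        return self.class_code in KNOWN_CLASSES

    def __str__(self) -> str:
        return format_lipid_name(self)


# head = class token plus optional modifiers.  Accepted dialects for the
# ether variant: "PC-O(...)" (canonical) and "PC O-(...)"; oxidized: suffix
# "ox" or "oxo".  Non-greedy class token so "TGox" splits as TG + ox.
_HEAD_RE = re.compile(
    r"^(?P<cls>[A-Za-z][A-Za-z0-9]*?)"
    r"(?P<ether>-O|\sO-)?"
    r"(?P<ox>oxo|ox)?$"
)
_COMP_RE = re.compile(r"^(?P<c>\d+):(?P<d>\d+)$")


def _parse_head(head: str, original: str) -> tuple[str, bool, bool]:
    m = _HEAD_RE.match(head.strip())
    if m is None:
        raise LipidNameError(f"cannot parse class token {head!r} in {original!r}")
    cls = m.group("cls")
    ether = m.group("ether") is not None
    oxid = m.group("ox") is not None
    if cls not in KNOWN_CLASSES:
        # second arg carries the bare token so readers can collect it
        warnings.warn(
            UnknownLipidClassWarning(f"unknown lipid class {cls!r} in {original!r}", cls),
            stacklevel=3,
        )
    return cls, ether, oxid


def _split(name: str) -> tuple[str, str]:
    name = name.strip()
    if not name:
        raise LipidNameError("empty lipid name")
    if not name.endswith(")") or "(" not in name:
        raise LipidNameError(f"no parenthesized composition in {name!r}")
    head, _, body = name[:-1].partition("(")
    if not body:
        raise LipidNameError(f"empty composition in {name!r}")
    return head, body


def _parse_comp(token: str, original: str) -> tuple[int, int]:
    m = _COMP_RE.match(token.strip())
    if m is None:
        raise LipidNameError(f"malformed composition token {token!r} in {original!r}")
    return int(m.group("c")), int(m.group("d"))


def parse_lipid_name(name: str) -> LipidName:
    """Parse one shorthand name such as ``"PC(34:2)"`` or ``"TG(17:0/17:0/17:0)"``.

    Raises :class:`LipidNameError` on malformed input; unknown class codes
    are accepted with an :class:`UnknownLipidClassWarning`.
    """
    head, body = _split(name)
    if "," in body:
        raise LipidNameError(
            f"{name!r} is a compact multi-species list; use expand_compact_list()"
        )
    cls, ether, oxid = _parse_head(head, name)
    if "/" in body:
        chains = tuple(_parse_comp(t, name) for t in body.split("/"))
        c = sum(ch[0] for ch in chains)
        d = sum(ch[1] for ch in chains)
        return LipidName(cls, c, d, ether, oxid, chains)
    c, d = _parse_comp(body, name)
    return LipidName(cls, c, d, ether, oxid)


def format_lipid_name(lipid: LipidName) -> str:
    """Canonical text form; inverse of :func:`parse_lipid_name`."""
    head = lipid.class_code
    if lipid.ether_flag:
        head += "-O"
    if lipid.oxidized_flag:
        head += "ox"
    if lipid.chains is not None:
        body = "/".join(f"{c}:{d}" for c, d in lipid.chains)
    else:
        body = f"{lipid.total_carbons}:{lipid.total_double_bonds}"
    return f"{head}({body})"


# double-bond ranges may be printed with an ASCII hyphen, en-dash or minus
_RANGE_RE = re.compile(r"^(?P<c>\d+):(?P<d1>\d+)[\-−–](?P<d2>\d+)$")


def expand_compact_list(text: str) -> list[LipidName]:
    """Expand compact multi-species notation into individual names.

    ``"TG(48:0, 48:1, 48:2)"`` lists several compositions of one class;
    ``"TG(54:3-6)"`` abbreviates a run of double-bond counts.  A single
    ordinary name expands to a one-element list.
    """
    head, body = _split(text)
    cls, ether, oxid = _parse_head(head, text)
    out: list[LipidName] = []
    for token in body.split(","):
        token = token.strip()
        if "(" in token or ")" in token:
            raise LipidNameError(f"mixed class prefixes inside one parenthesis: {text!r}")
        m = _RANGE_RE.match(token)
        if m is not None:
            c = int(m.group("c"))
            d1, d2 = int(m.group("d1")), int(m.group("d2"))
            if d2 < d1:
                raise LipidNameError(f"descending double-bond range {token!r}")
            for d in range(d1, d2 + 1):
                out.append(LipidName(cls, c, d, ether, oxid))
        elif "/" in token:
            chains = tuple(_parse_comp(t, text) for t in token.split("/"))
            c = sum(ch[0] for ch in chains)
            d = sum(ch[1] for ch in chains)
            out.append(LipidName(cls, c, d, ether, oxid, chains))
        else:
            c, d = _parse_comp(token, text)
            out.append(LipidName(cls, c, d, ether, oxid))
    return out


def lipid_class(name: LipidName | str, group_dg_with_tg: bool = False) -> str:
    """Class label used for grouping in count tables.

    With ``group_dg_with_tg`` the DG species that arise from in-source
    fragmentation of TGs during data collection are counted with the TGs,
    the convention used for triglyceride traffic plots.
    """
    if isinstance(name, str):
        name = parse_lipid_name(name)
    cls = name.class_code
    if group_dg_with_tg and cls == "DG":
        return "TG"
    return cls
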