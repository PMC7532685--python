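"""Phenotype definitions: +/- expression patterns over cytoplasm markers.

A phenotype is a nucleus (always required) plus a sign pattern over up to
three cytoplasm marker channels: ``'+'`` marker expressed, ``'-'`` marker
absent, ``'0'`` channel ignored.  Entries for channels beyond a field of
view's channel count are dropped when the pattern is applied.

The default registry enumerates 20 phenotypes: the nucleus-only class
(all available markers negative), the three single-marker positives, the
three channel pairs with each non-all-negative sign pattern, and the
seven non-all-negative triple-marker patterns.  The registry is a plain
mapping and can be replaced wholesale for assay-specific panels (see
:func:`ctc_registry`).
"""

from __future__ import annotations

from dataclasses import dataclass

SIGNS = ("+", "-", "0")


@dataclass(frozen=True)
class PhenotypeSpec:
    """A named marker-expression pattern; the nucleus channel is implicit."""

    name: str
    pattern: tuple[str, ...]  # one sign per marker channel slot (C1, C2, C3)

    def __post_init__(self):
        if len(self.pattern) > 3:
            raise ValueError("at most 3 marker channels are supported")
        if any(s not in SIGNS for s in self.pattern):
            raise ValueError(f"pattern signs must be in {SIGNS}")

    def active_pattern(self, n_channels: int) -> dict[int, str]:
        """Map channel index -> '+'/'-' restricted to available, non-ignored channels."""
        return {
            i: s
            for i, s in enumerate(self.pattern[:n_channels])
            if s != "0"
        }

    def expresses(self, channel: int) -> bool:
        return channel < len(self.pattern) and self.pattern[channel] == "+"


def default_registry() -> dict[str, PhenotypeSpec]:
    """The 20-phenotype default panel, P1..P20."""
    specs = [
        PhenotypeSpec("P1", ("-", "-", "-")),   # nucleus only
        PhenotypeSpec("P2", ("+", "0", "0")),
        PhenotypeSpec("P3", ("0", "+", "0")),
        PhenotypeSpec("P4", ("0", "0", "+")),
        PhenotypeSpec("P5", ("+", "+", "0")),
        PhenotypeSpec("P6", ("+", "-", "0")),
        PhenotypeSpec("P7", ("-", "+", "0")),
        PhenotypeSpec("P8", ("+", "0", "+")),
        PhenotypeSpec("P9", ("+", "0", "-")),
        PhenotypeSpec("P10", ("-", "0", "+")),
        PhenotypeSpec("P11", ("0", "+", "+")),
        PhenotypeSpec("P12", ("0", "+", "-")),
        PhenotypeSpec("P13", ("0", "-", "+")),
        PhenotypeSpec("P14", ("+", "+", "+")),
        PhenotypeSpec("P15", ("+", "+", "-")),
        PhenotypeSpec("P16", ("+", "-", "+")),
        PhenotypeSpec("P17", ("-", "+", "+")),
        PhenotypeSpec("P18", ("+", "-", "-")),
        PhenotypeSpec("P19", ("-", "+", "-")),
        PhenotypeSpec("P20", ("-", "-", "+")),
    ]
    return {s.name: s for s in specs}


def ctc_registry() -> dict[str, PhenotypeSpec]:
    """Liquid-biopsy panel with channel order (CD45, E-cadherin, vimentin)."""
    specs = [
        PhenotypeSpec("E-CTC", ("-", "+", "-")),
        PhenotypeSpec("M-CTC", ("-", "-", "+")),
        PhenotypeSpec("H-CTC", ("-", "+", "+")),
        PhenotypeSpec("CHC-1", ("+", "+", "-")),
        PhenotypeSpec("CHC-2", ("+", "+", "+")),
        PhenotypeSpec("WBC", ("+", "-", "-")),
    ]
    return {s.name: s for s in specs}


def _spec_matches(spec: PhenotypeSpec, channel_ids: tuple[int, ...],
                  signs: tuple[str, ...]) -> bool:
    """Does ``spec`` denote exactly the full pattern ``signs`` on this run?

    A run images the registry channels ``channel_ids`` in slot order.  The
    spec must agree on every imaged channel and must not require
    expression ('+') on a channel that is not imaged.
    """
    pat = spec.pattern + ("0",) * (3 - len(spec.pattern))
    for j, ch in enumerate(channel_ids):
        if pat[ch] != signs[j]:
            return False
    for ch in range(3):
        if ch not in channel_ids and pat[ch] == "+":
            return False
    return True


def full_patterns(channel_ids: tuple[int, ...],
                  registry: dict[str, PhenotypeSpec] | None = None
                  ) -> list[PhenotypeSpec]:
    """All 2^k full sign patterns for a run imaging ``channel_ids``.

    Each pattern is named after the first matching registry phenotype;
    patterns without a registry name get a synthetic ``pat:...`` name.
    The returned specs are expressed in run-slot order.
    """
    import itertools

    registry = default_registry() if registry is None else registry
    channel_ids = tuple(channel_ids)
    out = []
    for signs in itertools.product("+-", repeat=len(channel_ids)):
        name = next(
            (s.name for s in registry.values() if _spec_matches(s, channel_ids, signs)),
            "pat:" + "".join(signs),
        )
        out.append(PhenotypeSpec(name, signs))
    return out
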