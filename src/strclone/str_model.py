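"""Domain model for STR genotyping of clonal cell cultures.

A profile is the set of allele designations observed at each locus of a
forensic-style panel of 19 short-tandem-repeat loci (all tetranucleotide
repeats except the trinucleotide D22S1045) plus the amelogenin X/Y sex
marker. Alleles follow standard STR nomenclature: an integer full-repeat
count, optionally with a microvariant suffix giving extra nucleotides
(``9.3`` = nine full repeats plus three nucleotides).

The module ships two fixture sets: the panel metadata (locus, cytogenetic
band, repeat-unit length) and the reference profiles of the Jurkat
(T-lymphoblastic leukaemia) and WIL2-S (non-tumour B-lymphoblastoid) cell
lines, from the vendor (ATCC) catalogue where published and from in-house
typing for the full panel.

Amelogenin is modelled as two presence flags (X, Y), not repeat alleles:
the biologically relevant event at that locus is loss of the Y product.
A single-allele locus is stored exactly as observed; whether it reflects
homozygosity or hemizygosity is never imputed — "homozygous" is only ever
a property of a designated parental profile.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .errors import AlleleParseError, DataError, ValidationError

#: Canonical identifier for the amelogenin sex-marker locus.
AMELO = "AMELO"

#: Aliases accepted on input for the amelogenin locus.
_AMELO_ALIASES = {"AMELO", "AMELOGENIN", "AMEL"}

PANEL_VERSION = "v1"

_ALLELE_RE = re.compile(r"^(\d+)(?:\.(\d))?$")


# ---------------------------------------------------------------------------
# Allele calls
# ---------------------------------------------------------------------------

@dataclass(frozen=True, order=True)
class AlleleCall:
    """One STR allele designation: full repeats plus microvariant nucleotides.

    Ordering by ``(repeats, partial_nt)`` coincides with ordering by
    fragment length within a locus, because ``partial_nt`` is always
    smaller than the repeat unit.
    """

    repeats: int
    partial_nt: int = 0

    def __post_init__(self) -> None:
        if self.repeats < 1:
            raise ValidationError(f"allele repeats must be >= 1, got {self.repeats}")
        if not 0 <= self.partial_nt <= 3:
            raise ValidationError(
                f"allele partial_nt must be in 0..3, got {self.partial_nt}"
            )

    def length_nt(self, unit_nt: int) -> int:
        """Amplicon repeat-region length in nucleotides at a locus with the
        given repeat-unit size."""
        return self.repeats * unit_nt + self.partial_nt

    def shifted(self, units: int) -> "AlleleCall":
        """The allele shifted by a whole number of repeat units."""
        return AlleleCall(self.repeats + units, self.partial_nt)

    def __str__(self) -> str:
        if self.partial_nt:
            return f"{self.repeats}.{self.partial_nt}"
        return str(self.repeats)


def parse_allele(text: str) -> AlleleCall:
    """Parse an allele designation such as ``"14"`` or ``"9.3"``.

    Raises :class:`AlleleParseError` naming the offending token for
    anything that is not ``N`` or ``N.m`` with ``m`` in 1..3.
    """
    m = _ALLELE_RE.match(text.strip())
    if m is None:
        raise AlleleParseError(f"malformed allele designation: {text!r}")
    repeats = int(m.group(1))
    partial = int(m.group(2)) if m.group(2) else 0
    if repeats < 1:
        raise AlleleParseError(f"malformed allele designation: {text!r}")
    if partial and not 1 <= partial <= 3:
        raise AlleleParseError(
            f"malformed allele designation: {text!r} (microvariant must be .1-.3)"
        )
    return AlleleCall(repeats, partial)


def format_alleles(alleles: Iterable[AlleleCall]) -> str:
    """Comma-joined designations in ascending length order, e.g. ``"8,9.3"``."""
    return ",".join(str(a) for a in sorted(alleles))


def parse_allele_set(text: str) -> frozenset[AlleleCall]:
    if not text.strip():
        return frozenset()
    return frozenset(parse_allele(tok) for tok in text.split(","))


# ---------------------------------------------------------------------------
# Locus panel
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LocusDef:
    """One locus of the typing panel."""

    name: str
    band: str
    unit_nt: int
    is_amelogenin: bool = False

    def __post_init__(self) -> None:
        if not self.is_amelogenin and self.unit_nt not in (3, 4):
            raise ValidationError(
                f"STR locus {self.name}: repeat unit must be 3 or 4 nt, "
                f"got {self.unit_nt}"
            )


class LocusPanel:
    """Ordered collection of locus definitions with name lookup."""

    def __init__(self, loci: Iterable[LocusDef]):
        self.loci: tuple[LocusDef, ...] = tuple(loci)
        self._by_name = {l.name: l for l in self.loci}
        if len(self._by_name) != len(self.loci):
            raise ValidationError("duplicate locus names in panel")

    def __len__(self) -> int:
        return len(self.loci)

    def __iter__(self):
        return iter(self.loci)

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def __getitem__(self, name: str) -> LocusDef:
        try:
            return self._by_name[name]
        except KeyError:
            raise KeyError(f"locus {name!r} not in panel") from None

    @property
    def str_loci(self) -> tuple[LocusDef, ...]:
        """The repeat loci, excluding amelogenin, in panel order."""
        return tuple(l for l in self.loci if not l.is_amelogenin)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(l.name for l in self.loci)


def load_panel() -> LocusPanel:
    """Load the packaged 19-STR-locus + amelogenin panel metadata."""
    path = resources.files("strclone.data") / f"panel_{PANEL_VERSION}.csv"
    with resources.as_file(path) as p:
        df = pd.read_csv(p)
    loci = [
        LocusDef(
            name=row.locus,
            band=row.band,
            unit_nt=int(row.unit_nt),
            is_amelogenin=row.locus == AMELO,
        )
        for row in df.itertuples()
    ]
    return LocusPanel(loci)


# ---------------------------------------------------------------------------
# Profiles
# ---------------------------------------------------------------------------

@dataclass
class STRProfile:
    """Observed allele sets of one clone, plus amelogenin X/Y flags.

    ``calls`` maps STR locus name to an unordered set of allele calls
    (normally 1–3 per locus; an empty set encodes locus dropout and is
    rejected by the comparison stage as a non-biological null).
    """

    clone_id: str
    calls: dict[str, frozenset[AlleleCall]] = field(default_factory=dict)
    amelo_x: bool = True
    amelo_y: bool = False

    @classmethod
    def from_strings(
        cls, clone_id: str, designations: Mapping[str, str]
    ) -> "STRProfile":
        """Build a profile from ``{locus: "22,23", ..., "AMELO": "X,Y"}``."""
        calls: dict[str, frozenset[AlleleCall]] = {}
        amelo_x = amelo_y = False
        have_amelo = False
        for locus, text in designations.items():
            if locus.upper() in _AMELO_ALIASES:
                have_amelo = True
                toks = {t.strip().upper() for t in text.split(",") if t.strip()}
                bad = toks - {"X", "Y"}
                if bad:
                    raise AlleleParseError(
                        f"{clone_id}: amelogenin calls must be X/Y, got {sorted(bad)}"
                    )
                amelo_x = "X" in toks
                amelo_y = "Y" in toks
            else:
                calls[locus] = parse_allele_set(text)
        if not have_amelo:
            amelo_x = True
        return cls(clone_id=clone_id, calls=calls, amelo_x=amelo_x, amelo_y=amelo_y)

    def validate(self, panel: LocusPanel) -> None:
        """Check locus names and allele-set sizes against the panel."""
        for locus, alleles in self.calls.items():
            if locus not in panel:
                raise DataError(f"{self.clone_id}: unknown locus {locus!r}")
            if panel[locus].is_amelogenin:
                raise DataError(
                    f"{self.clone_id}: amelogenin must use the X/Y flags"
                )
            if len(alleles) > 3:
                raise DataError(
                    f"{self.clone_id}: {locus} has {len(alleles)} alleles (max 3)"
                )
            unit = panel[locus].unit_nt
            for a in alleles:
                if a.partial_nt >= unit:
                    raise DataError(
                        f"{self.clone_id}: {locus} allele {a} has microvariant "
                        f"{a.partial_nt} nt >= repeat unit {unit} nt"
                    )

    def is_heterozygous(self, locus: str) -> bool:
        return len(self.calls.get(locus, frozenset())) >= 2

    def amelo_string(self) -> str:
        return ",".join(s for s, flag in (("X", self.amelo_x), ("Y", self.amelo_y)) if flag)


def reference_profile(line: str, source: str) -> STRProfile:
    """Packaged reference profile of ``JURKAT`` or ``WIL2S``.

    ``source="ATCC"`` returns only the loci in the vendor catalogue (nine
    STR loci plus amelogenin); ``source="OWN"`` covers the full panel.
    Loci absent from a source are absent from ``calls``.
    """
    line = line.upper()
    source = source.upper()
    if line not in {"JURKAT", "WIL2S"}:
        raise ValidationError(f"unknown cell line {line!r} (JURKAT or WIL2S)")
    if source not in {"ATCC", "OWN"}:
        raise ValidationError(f"unknown profile source {source!r} (ATCC or OWN)")
    path = resources.files("strclone.data") / "reference_profiles.tsv"
    with resources.as_file(path) as p:
        df = pd.read_csv(p, sep="\t", dtype=str)
    sub = df[(df["line"] == line) & (df["source"] == source)]
    designations = dict(zip(sub["locus"], sub["alleles"]))
    return STRProfile.from_strings(f"{line}-{source}", designations)


# ---------------------------------------------------------------------------
# Genotype table I/O (long-form TSV)
# ---------------------------------------------------------------------------

GENOTYPE_COLUMNS = ("clone_id", "locus", "alleles")


def write_genotype_table(
    profiles: Iterable[STRProfile], path: str | Path, panel: LocusPanel
) -> None:
    """Write profiles as a long-form TSV (clone_id, locus, alleles).

    Loci are emitted in panel order; the amelogenin row carries ``X,Y`` /
    ``X``. Round-trips bit-exactly with :func:`read_genotype_table`.
    """
    rows = []
    for prof in profiles:
        for locus in panel:
            if locus.is_amelogenin:
                rows.append((prof.clone_id, AMELO, prof.amelo_string()))
            elif locus.name in prof.calls:
                rows.append(
                    (prof.clone_id, locus.name, format_alleles(prof.calls[locus.name]))
                )
    df = pd.DataFrame(rows, columns=GENOTYPE_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def read_genotype_table(path: str | Path, panel: LocusPanel) -> list[STRProfile]:
    """Read a long-form genotype TSV into profiles, in first-appearance order."""
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise DataError(f"cannot read genotype table {path}: {exc}") from exc
    missing = set(GENOTYPE_COLUMNS) - set(df.columns)
    if missing:
        raise DataError(
            f"genotype table {path} lacks required columns {sorted(missing)}"
        )
    profiles: dict[str, dict[str, str]] = {}
    for i, row in enumerate(df.itertuples(), start=2):
        clone, locus, alleles = row.clone_id, row.locus, row.alleles
        if not clone or not locus:
            raise DataError(f"{path}:{i}: empty clone_id or locus")
        try:
            if locus.upper() not in _AMELO_ALIASES:
                parse_allele_set(alleles)
        except AlleleParseError as exc:
            raise DataError(f"{path}:{i}: {exc}") from exc
        profiles.setdefault(clone, {})[locus] = alleles
    out = []
    for clone_id, designations in profiles.items():
        prof = STRProfile.from_strings(clone_id, designations)
        prof.validate(panel)
        out.append(prof)
    return out
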