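"""Stimulus spaces for colour naming: the WCS Munsell palette and synthetic grids.

The World Colour Survey (WCS) palette is a set of 330 Munsell chips arranged on
a 2-D grid -- ten lightness rows labelled A--J and hue columns 0--40, where
column 0 holds the achromatic chips -- each embedded in 3-D CIELAB space
(L*, a*, b*).  Perceptual dissimilarity between chips is approximated by
squared Euclidean distance in CIELAB, which is all the downstream efficiency
model needs from the stimulus space.

Synthetic grid universes share the same structure (row letters, hue-like
columns, a CIELAB embedding) so that every downstream component runs
identically on real and generated data.
"""

from __future__ import annotations

import io
import string
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Chip",
    "Universe",
    "FormatError",
    "load_wcs_palette",
    "load_wcs_naming",
    "make_grid_universe",
    "write_chip_table",
    "write_lab_table",
]

WCS_N_CHIPS = 330
WCS_ROWS = "ABCDEFGHIJ"
WCS_MAX_COL = 40


class FormatError(ValueError):
    """Raised when an input table violates the documented WCS dialect."""


@dataclass(frozen=True)
class Chip:
    """One colour stimulus: grid position plus CIELAB coordinates."""

    id: int
    grid_row: str
    grid_col: int
    lab: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "lab", np.asarray(self.lab, dtype=float))
        if self.lab.shape != (3,):
            raise ValueError(f"chip {self.id}: lab must be a 3-vector")


@dataclass
class Universe:
    """An ordered set of chips with pairwise squared CIELAB distances.

    Attributes
    ----------
    chips : list of Chip
        Stimuli in canonical order; downstream matrices index chips by
        position in this list.
    sqdist : ndarray of shape (n, n)
        Squared Euclidean distances between CIELAB coordinates.
    """

    chips: list[Chip]
    sqdist: np.ndarray = field(init=False, repr=False)

    def __post_init__(self):
        lab = self.lab
        diff = lab[:, None, :] - lab[None, :, :]
        self.sqdist = np.einsum("ijk,ijk->ij", diff, diff)
        seen = {}
        for c in self.chips:
            key = (c.grid_row, c.grid_col)
            if key in seen:
                raise FormatError(f"duplicate grid position {key}")
            seen[key] = c.id
        # coincident chips are legal but suspicious
        off = self.sqdist + np.where(np.eye(len(self.chips)) > 0, np.inf, 0.0)
        if len(self.chips) > 1 and np.min(off) == 0.0:
            warnings.warn("universe contains chips with identical CIELAB coordinates")

    @property
    def n_chips(self) -> int:
        return len(self.chips)

    @property
    def lab(self) -> np.ndarray:
        return np.array([c.lab for c in self.chips])

    @property
    def ids(self) -> np.ndarray:
        return np.array([c.id for c in self.chips])

    def index_of(self, chip_id: int) -> int:
        try:
            return int(np.flatnonzero(self.ids == chip_id)[0])
        except IndexError:
            raise KeyError(f"chip id {chip_id} not in universe") from None

    def grid_index(self) -> dict[tuple[str, int], int]:
        """Map (row letter, column) -> position in ``chips``."""
        return {(c.grid_row, c.grid_col): i for i, c in enumerate(self.chips)}


def _read_table(src, **kw) -> pd.DataFrame:
    if isinstance(src, str) and "\t" in src:
        src = io.StringIO(src)
    return pd.read_csv(src, sep="\t", **kw)


def load_wcs_palette(chip_table, lab_table) -> Universe:
    """Build the WCS universe from its two published tables.

    Parameters
    ----------
    chip_table : path, file-like or TSV string
        ``chip.txt`` dialect: tab-separated, no header, columns
        ``(chip id, row letter A--J, column 0--40, row-column code)``; the
        fourth column is ignored if present.
    lab_table : path, file-like or TSV string
        ``cnum-vhcm-lab-new.txt`` dialect: tab-separated with a header line;
        the chip id column is named ``#cnum`` and the CIELAB columns
        ``L*``, ``a*``, ``b*``.

    Returns
    -------
    Universe
        All 330 chips in chip-id order with the CIELAB distance matrix.
    """
    chips_df = _read_table(chip_table, header=None)
    if chips_df.shape[1] < 3:
        raise FormatError("chip table needs at least 3 columns (id, row, col)")
    chips_df = chips_df.iloc[:, :3]
    chips_df.columns = ["id", "row", "col"]

    lab_df = _read_table(lab_table)
    lab_cols = {c.strip(): c for c in lab_df.columns}
    try:
        id_col = lab_cols["#cnum"]
        l_col, a_col, b_col = lab_cols["L*"], lab_cols["a*"], lab_cols["b*"]
    except KeyError as e:
        raise FormatError(f"lab table missing expected column {e}") from None
    lab_map = {
        int(r[id_col]): np.array([r[l_col], r[a_col], r[b_col]], dtype=float)
        for _, r in lab_df.iterrows()
    }

    ids = chips_df["id"].astype(int)
    if ids.duplicated().any():
        raise FormatError(f"duplicate chip ids: {sorted(ids[ids.duplicated()])}")
    expected = set(range(1, WCS_N_CHIPS + 1))
    got = set(ids)
    if got != expected:
        missing = sorted(expected - got)[:5]
        extra = sorted(got - expected)[:5]
        raise FormatError(f"chip table must cover ids 1..330; missing {missing}, extra {extra}")

    chips = []
    for _, r in chips_df.sort_values("id").iterrows():
        cid, row, col = int(r["id"]), str(r["row"]).strip(), int(r["col"])
        if row not in WCS_ROWS:
            raise FormatError(f"chip {cid}: row {row!r} outside A-J")
        if not (0 <= col <= WCS_MAX_COL):
            raise FormatError(f"chip {cid}: column {col} outside 0-40")
        if cid not in lab_map:
            raise FormatError(f"chip {cid} has no CIELAB entry")
        chips.append(Chip(cid, row, col, lab_map[cid]))
    return Universe(chips)


def load_wcs_naming(term_table, universe: Universe, language_id):
    """Estimate a language's naming distribution q(w|c) from elicitation records.

    ``term_table`` follows the WCS ``term.txt`` dialect: tab-separated, no
    header, columns ``(language id, speaker id, chip id, term)``.  Each record
    counts once; q(w|c) is the fraction of the language's records for chip c
    that used term w.

    Returns a :class:`~colornaming.ib.NamingSystem` over ``universe``.
    """
    from .ib import NamingSystem

    df = _read_table(term_table, header=None)
    if df.shape[1] < 4:
        raise FormatError("term table needs 4 columns (language, speaker, chip, term)")
    df = df.iloc[:, :4]
    df.columns = ["language", "speaker", "chip", "term"]
    sub = df[df["language"].astype(str) == str(language_id)]
    if sub.empty:
        raise KeyError(f"no records for language {language_id!r}")

    terms = sorted(sub["term"].astype(str).unique())
    t_index = {t: j for j, t in enumerate(terms)}
    counts = np.zeros((universe.n_chips, len(terms)))
    for _, r in sub.iterrows():
        cid = int(r["chip"])
        i = universe.index_of(cid)  # raises KeyError for chips outside the universe
        counts[i, t_index[str(r["term"])]] += 1
    row_sums = counts.sum(axis=1)
    unnamed = np.flatnonzero(row_sums == 0)
    if unnamed.size:
        bad = [universe.chips[i].id for i in unnamed[:5]]
        raise FormatError(f"language {language_id!r}: chips never named, e.g. {bad}")
    return NamingSystem(counts / row_sums[:, None], terms)


def make_grid_universe(n_rows: int, n_cols: int, spacing: float = 10.0) -> Universe:
    """Synthetic stand-in for the WCS palette: a regular 2-D grid in CIELAB.

    Chips sit at a fixed lightness L* = 50 with a* spaced along columns and
    b* along rows, so nearest grid neighbours are ``spacing`` CIELAB units
    apart.  Columns are numbered from 1 (all chips "chromatic"), rows
    labelled A, B, ... as in the WCS.
    """
    if n_rows < 1 or n_cols < 1:
        raise ValueError("grid dimensions must be >= 1")
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    if n_rows > len(string.ascii_uppercase):
        raise ValueError("at most 26 rows supported (row labels are letters)")
    chips = []
    cid = 1
    for r in range(n_rows):
        for c in range(n_cols):
            lab = np.array([50.0, c * spacing, r * spacing])
            chips.append(Chip(cid, string.ascii_uppercase[r], c + 1, lab))
            cid += 1
    return Universe(chips)


def write_chip_table(universe: Universe) -> str:
    """Serialise chip positions in the ``chip.txt`` dialect (TSV, no header)."""
    lines = [
        f"{c.id}\t{c.grid_row}\t{c.grid_col}\t{c.grid_row}{c.grid_col}"
        for c in universe.chips
    ]
    return "\n".join(lines) + "\n"


def write_lab_table(universe: Universe) -> str:
    """Serialise CIELAB coordinates in the ``cnum-vhcm-lab-new.txt`` dialect."""
    lines = ["#cnum\tL*\ta*\tb*"]
    for c in universe.chips:
        lines.append(f"{c.id}\t{c.lab[0]:.17g}\t{c.lab[1]:.17g}\t{c.lab[2]:.17g}")
    return "\n".join(lines) + "\n"


def load_grid_universe(chip_table, lab_table) -> Universe:
    """Round-trip loader for synthetic universes in the WCS dialects.

    Unlike :func:`load_wcs_palette` this does not require the full 330-chip
    palette; it accepts any consistent grid.
    """
    chips_df = _read_table(chip_table, header=None).iloc[:, :3]
    chips_df.columns = ["id", "row", "col"]
    lab_df = _read_table(lab_table)
    lab_cols = {c.strip(): c for c in lab_df.columns}
    id_col, l_col, a_col, b_col = (lab_cols[k] for k in ("#cnum", "L*", "a*", "b*"))
    lab_map = {
        int(r[id_col]): np.array([r[l_col], r[a_col], r[b_col]], dtype=float)
        for _, r in lab_df.iterrows()
    }
    if chips_df["id"].duplicated().any():
        raise FormatError("duplicate chip ids")
    chips = []
    for _, r in chips_df.sort_values("id").iterrows():
        cid = int(r["id"])
        if cid not in lab_map:
            raise FormatError(f"chip {cid} has no CIELAB entry")
        chips.append(Chip(cid, str(r["row"]).strip(), int(r["col"]), lab_map[cid]))
    return Universe(chips)
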