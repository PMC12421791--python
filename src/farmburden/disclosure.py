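"""Statistical disclosure control for published cross-tabulations.

The publication conventions implemented here are the ones used for
small-cell confidentiality in Australian coronial and workers'
compensation outputs:

* **threshold suppression** — any cell with a count of 1..4 is replaced by
  the marker ``np`` ("not for publication"); zero cells stay visible;
* **complementary masking** — where a suppressed value could be recovered
  by subtraction from a visible line total, a further cell is masked with
  ``+`` (a value of five or more, withheld to retain confidentiality);
* **multiple-based rounding** — visible values are rounded to a configured
  multiple (5 for counts, 5,000 for monetary averages, ...) at render time
  only; all internal totals are true totals.

The complementary-masking rule is a deterministic fixpoint heuristic (mask
the smallest visible cell in any line whose only masked cell is an ``np``
and whose total is visible), backed by an exact recoverability audit on
small tables: if integer enumeration over all completions consistent with
the visible cells and totals pins an ``np`` cell to a unique value, further
cells — or, as a last resort, the line total itself — are masked until no
suppressed cell is recoverable.
"""

from __future__ import annotations

import csv
import io
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

NP_MARKER = "np"
PLUS_MARKER = "+"

#: Node budget for the exact recoverability audit; tables whose masked-cell
#: search space exceeds this are left with the heuristic masking only.
_AUDIT_NODE_BUDGET = 500_000


def round_to_multiple(x: float, m: float) -> float:
    """Round ``x`` to the nearest multiple of ``m``; ties round away from zero.

    Idempotent on exact multiples.  Returns an ``int`` whenever ``m`` is a
    whole number.
    """
    if m <= 0:
        raise ValueError(f"rounding multiple must be positive, got {m}")
    sign = -1.0 if x < 0 else 1.0
    q = math.floor(abs(x) / m + 0.5)
    result = sign * q * m
    if float(m).is_integer():
        return int(result)
    return result


@dataclass
class MaskedTable:
    """A cross-tabulation with disclosure markers over true counts.

    ``true`` holds the unmasked integer counts; ``mask`` holds ``None`` for
    a visible cell, :data:`NP_MARKER` for a suppressed small cell or
    :data:`PLUS_MARKER` for a complementarily masked cell.  Row, column and
    grand totals are always computed from the true counts (rounding and
    masking are presentation concerns); a total itself may carry a ``+``
    marker when it must be withheld to protect a suppressed cell.
    """

    row_labels: list[str]
    col_labels: list[str]
    true: np.ndarray
    mask: np.ndarray
    row_total_mask: np.ndarray = None  # type: ignore[assignment]
    col_total_mask: np.ndarray = None  # type: ignore[assignment]
    grand_total_masked: bool = False
    threshold: int = 5
    rounding_multiple: float = 1
    name: str = "table"

    def __post_init__(self) -> None:
        self.true = np.asarray(self.true, dtype=np.int64)
        if self.true.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValueError("count matrix shape does not match axis labels")
        if (self.true < 0).any():
            raise ValueError("cell counts must be non-negative")
        if self.mask is None:
            self.mask = np.full(self.true.shape, None, dtype=object)
        self.mask = np.asarray(self.mask, dtype=object)
        if self.row_total_mask is None:
            self.row_total_mask = np.full(len(self.row_labels), None, dtype=object)
        if self.col_total_mask is None:
            self.col_total_mask = np.full(len(self.col_labels), None, dtype=object)

    # -- construction ------------------------------------------------------

    @classmethod
    def from_counts(
        cls,
        counts: pd.DataFrame,
        threshold: int = 5,
        rounding_multiple: float = 1,
        name: str = "table",
    ) -> "MaskedTable":
        return cls(
            row_labels=[str(r) for r in counts.index],
            col_labels=[str(c) for c in counts.columns],
            true=counts.to_numpy(),
            mask=None,
            threshold=threshold,
            rounding_multiple=rounding_multiple,
            name=name,
        )

    def copy(self) -> "MaskedTable":
        return MaskedTable(
            row_labels=list(self.row_labels),
            col_labels=list(self.col_labels),
            true=self.true.copy(),
            mask=self.mask.copy(),
            row_total_mask=self.row_total_mask.copy(),
            col_total_mask=self.col_total_mask.copy(),
            grand_total_masked=self.grand_total_masked,
            threshold=self.threshold,
            rounding_multiple=self.rounding_multiple,
            name=self.name,
        )

    # -- true totals (never masked internally) -----------------------------

    @property
    def row_totals(self) -> np.ndarray:
        return self.true.sum(axis=1)

    @property
    def col_totals(self) -> np.ndarray:
        return self.true.sum(axis=0)

    @property
    def grand_total(self) -> int:
        return int(self.true.sum())

    def validate(self) -> None:
        for i in range(self.true.shape[0]):
            for j in range(self.true.shape[1]):
                v, m = int(self.true[i, j]), self.mask[i, j]
                if m is None and 0 < v < self.threshold:
                    raise ValueError(
                        f"visible cell ({self.row_labels[i]}, {self.col_labels[j]}) "
                        f"has suppressible count {v}"
                    )
                if m == NP_MARKER and not 0 < v < self.threshold:
                    raise ValueError(
                        f"np marker on cell with count {v} (expected 1..{self.threshold - 1})"
                    )

    def to_frame(self) -> pd.DataFrame:
        """Rendered values (markers as strings, counts rounded) with totals."""
        if not self.row_labels:
            return pd.DataFrame(columns=["category", *self.col_labels, "Total"])
        mult = self.rounding_multiple

        def cell(i: int, j: int) -> str:
            if self.mask[i, j] is not None:
                return str(self.mask[i, j])
            return str(round_to_multiple(int(self.true[i, j]), mult))

        data = []
        for i, rl in enumerate(self.row_labels):
            row = [cell(i, j) for j in range(len(self.col_labels))]
            total = (
                PLUS_MARKER
                if self.row_total_mask[i] is not None
                else str(round_to_multiple(int(self.row_totals[i]), mult))
            )
            data.append([rl, *row, total])
        totals_row = [
            PLUS_MARKER
            if self.col_total_mask[j] is not None
            else str(round_to_multiple(int(self.col_totals[j]), mult))
            for j in range(len(self.col_labels))
        ]
        grand = (
            PLUS_MARKER
            if self.grand_total_masked
            else str(round_to_multiple(self.grand_total, mult))
        )
        data.append(["Total", *totals_row, grand])
        return pd.DataFrame(data, columns=["category", *self.col_labels, "Total"])


def suppress_small_cells(
    table: MaskedTable | pd.DataFrame, threshold: int = 5, **kwargs
) -> MaskedTable:
    """Mark every cell with a count of 1..threshold-1 as ``np``.

    Zeros remain visible (a published zero is not disclosive).  Existing
    ``+`` markers on a :class:`MaskedTable` input are preserved, which makes
    the full masking pipeline idempotent.
    """
    mt = (
        table.copy()
        if isinstance(table, MaskedTable)
        else MaskedTable.from_counts(table, threshold=threshold, **kwargs)
    )
    mt.threshold = threshold
    for i in range(mt.true.shape[0]):
        for j in range(mt.true.shape[1]):
            if 0 < mt.true[i, j] < threshold:
                mt.mask[i, j] = NP_MARKER
            elif mt.mask[i, j] == NP_MARKER:
                mt.mask[i, j] = None
    return mt


def complementary_suppress(table: MaskedTable, audit: bool = True) -> MaskedTable:
    """Add ``+`` markers so suppressed cells cannot be recovered by subtraction.

    First applies the line rule to fixpoint: in any row or column whose only
    masked cell is an ``np`` and whose total is visible, the smallest
    visible cell with a count of at least ``threshold`` is masked.  When
    ``audit`` is true and the table is small enough, an exact enumeration
    then checks every ``np`` cell for unique recoverability from the visible
    cells and totals jointly, masking further cells (or line totals, as the
    published tables themselves do) until none is recoverable.
    """
    mt = table.copy()
    _line_rule_fixpoint(mt)
    if audit:
        _audit_and_repair(mt)
    return mt


def _line_candidates(mt: MaskedTable, cells: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Visible cells in a line eligible for complementary masking, smallest
    count first, ties broken by category order."""
    eligible = [
        (int(mt.true[i, j]), i, j)
        for i, j in cells
        if mt.mask[i, j] is None and mt.true[i, j] >= mt.threshold
    ]
    eligible.sort(key=lambda t: (t[0], t[1], t[2]))
    return [(i, j) for _, i, j in eligible]


def _line_rule_fixpoint(mt: MaskedTable) -> None:
    n_rows, n_cols = mt.true.shape
    changed = True
    while changed:
        changed = False
        for i in range(n_rows):
            if mt.row_total_mask[i] is not None:
                continue
            cells = [(i, j) for j in range(n_cols)]
            masked = [c for c in cells if mt.mask[c] is not None]
            if len(masked) == 1 and mt.mask[masked[0]] == NP_MARKER:
                cand = _line_candidates(mt, cells)
                if cand:
                    mt.mask[cand[0]] = PLUS_MARKER
                else:
                    # no cell can absorb the mask: withhold the line total,
                    # as the published tables do for their sparse rows
                    mt.row_total_mask[i] = PLUS_MARKER
                changed = True
        for j in range(n_cols):
            if mt.col_total_mask[j] is not None:
                continue
            cells = [(i, j) for i in range(n_rows)]
            masked = [c for c in cells if mt.mask[c] is not None]
            if len(masked) == 1 and mt.mask[masked[0]] == NP_MARKER:
                cand = _line_candidates(mt, cells)
                if cand:
                    mt.mask[cand[0]] = PLUS_MARKER
                else:
                    mt.col_total_mask[j] = PLUS_MARKER
                changed = True


# -- exact recoverability audit --------------------------------------------

def feasible_values(
    mt: MaskedTable, target: tuple[int, int], stop_at: int | None = None
) -> set[int]:
    """All values the masked ``target`` cell can take in an integer completion
    consistent with the visible cells and visible (true) totals.

    Enumerates by depth-first search with partial-sum pruning; stops early
    once ``stop_at`` distinct values are found (enough to establish
    non-uniqueness); raises :class:`RuntimeError` if the node budget is
    exhausted.
    """
    n_rows, n_cols = mt.true.shape
    unknowns = [
        (i, j)
        for i in range(n_rows)
        for j in range(n_cols)
        if mt.mask[i, j] is not None
    ]
    if target not in unknowns:
        return {int(mt.true[target])}
    grand = mt.grand_total

    def bounds(i: int, j: int) -> tuple[int, int]:
        if mt.mask[i, j] == NP_MARKER:
            return 1, mt.threshold - 1
        upper = grand
        if mt.row_total_mask[i] is None:
            upper = min(upper, int(mt.row_totals[i]))
        if mt.col_total_mask[j] is None:
            upper = min(upper, int(mt.col_totals[j]))
        return mt.threshold, upper

    # order unknowns row-major so each row's total constraint closes early
    unknowns.sort()
    n_unknown = len(unknowns)
    row_acc = [
        sum(int(mt.true[i, j]) for j in range(n_cols) if mt.mask[i, j] is None)
        for i in range(n_rows)
    ]
    col_acc = [
        sum(int(mt.true[i, j]) for i in range(n_rows) if mt.mask[i, j] is None)
        for j in range(n_cols)
    ]
    all_bounds = [bounds(i, j) for i, j in unknowns]
    # suffix capacity of the still-unassigned unknowns, per column and overall,
    # so infeasible branches are cut long before the leaf
    col_min = [[0] * (n_unknown + 1) for _ in range(n_cols)]
    col_max = [[0] * (n_unknown + 1) for _ in range(n_cols)]
    glob_min = [0] * (n_unknown + 1)
    glob_max = [0] * (n_unknown + 1)
    for k in range(n_unknown - 1, -1, -1):
        _, j = unknowns[k]
        lo, hi = all_bounds[k]
        for jj in range(n_cols):
            col_min[jj][k] = col_min[jj][k + 1] + (lo if jj == j else 0)
            col_max[jj][k] = col_max[jj][k + 1] + (hi if jj == j else 0)
        glob_min[k] = glob_min[k + 1] + lo
        glob_max[k] = glob_max[k + 1] + hi
    values: set[int] = set()
    nodes = 0

    def last_unknown_in_row(k: int) -> bool:
        return k + 1 >= n_unknown or unknowns[k + 1][0] != unknowns[k][0]

    def dfs(k: int, assigned: dict, total_acc: int) -> None:
        nonlocal nodes
        nodes += 1
        if nodes > _AUDIT_NODE_BUDGET:
            raise RuntimeError("audit node budget exhausted")
        if k == n_unknown:
            for j in range(n_cols):
                if mt.col_total_mask[j] is None and col_acc[j] != mt.col_totals[j]:
                    return
            if not mt.grand_total_masked and total_acc != grand:
                return
            values.add(assigned[target])
            if stop_at is not None and len(values) >= stop_at:
                raise StopIteration
            return
        i, j = unknowns[k]
        lo, hi = all_bounds[k]
        for v in range(lo, hi + 1):
            if mt.row_total_mask[i] is None:
                if row_acc[i] + v > mt.row_totals[i]:
                    break
                if last_unknown_in_row(k) and row_acc[i] + v != mt.row_totals[i]:
                    continue
            if mt.col_total_mask[j] is None:
                ct = int(mt.col_totals[j])
                if not (
                    col_acc[j] + v + col_min[j][k + 1]
                    <= ct
                    <= col_acc[j] + v + col_max[j][k + 1]
                ):
                    continue
            if not mt.grand_total_masked and not (
                total_acc + v + glob_min[k + 1] <= grand <= total_acc + v + glob_max[k + 1]
            ):
                continue
            row_acc[i] += v
            col_acc[j] += v
            assigned[(i, j)] = v
            dfs(k + 1, assigned, total_acc + v)
            del assigned[(i, j)]
            row_acc[i] -= v
            col_acc[j] -= v

    try:
        dfs(0, {}, sum(row_acc))
    except StopIteration:
        pass
    return values


def _audit_and_repair(mt: MaskedTable) -> None:
    """Mask further cells/totals until no ``np`` cell is uniquely determined."""
    while True:
        vulnerable = None
        try:
            for i in range(mt.true.shape[0]):
                for j in range(mt.true.shape[1]):
                    if mt.mask[i, j] == NP_MARKER:
                        if len(feasible_values(mt, (i, j), stop_at=2)) <= 1:
                            vulnerable = (i, j)
                            raise StopIteration
        except StopIteration:
            pass
        except RuntimeError:
            return  # table too large for the exact audit; heuristic stands
        if vulnerable is None:
            return
        i, j = vulnerable
        row_cells = [(i, jj) for jj in range(mt.true.shape[1])]
        col_cells = [(ii, j) for ii in range(mt.true.shape[0])]
        cand = _line_candidates(mt, row_cells) or _line_candidates(mt, col_cells)
        if cand:
            mt.mask[cand[0]] = PLUS_MARKER
        elif mt.row_total_mask[i] is None:
            mt.row_total_mask[i] = PLUS_MARKER
        elif mt.col_total_mask[j] is None:
            mt.col_total_mask[j] = PLUS_MARKER
        elif not mt.grand_total_masked:
            mt.grand_total_masked = True
        else:
            return  # nothing left to withhold


def apply_disclosure(
    counts: pd.DataFrame | MaskedTable,
    threshold: int = 5,
    rounding_multiple: float = 1,
    audit: bool = True,
    name: str = "table",
) -> MaskedTable:
    """Full masking pipeline: threshold suppression then complementary masking."""
    if isinstance(counts, MaskedTable):
        mt = suppress_small_cells(counts, threshold=threshold)
    else:
        mt = suppress_small_cells(
            counts, threshold=threshold, rounding_multiple=rounding_multiple, name=name
        )
    return complementary_suppress(mt, audit=audit)


# -- rendering --------------------------------------------------------------

def render_table(table: MaskedTable, fmt: str = "markdown") -> str:
    """Render a masked table as CSV or Markdown text.

    Rounding to the table's configured multiple happens here and only here;
    markers are emitted exactly as ``np`` and ``+``.
    """
    frame = table.to_frame()
    if fmt == "csv":
        buf = io.StringIO()
        writer = csv.writer(buf, lineterminator="\n")
        writer.writerow(frame.columns.tolist())
        for row in frame.itertuples(index=False):
            writer.writerow(list(row))
        return buf.getvalue()
    if fmt == "markdown":
        headers = frame.columns.tolist()
        widths = [
            max(len(str(h)), *(len(str(v)) for v in frame[h])) for h in headers
        ] if len(frame) else [len(str(h)) for h in headers]
        lines = [
            "| " + " | ".join(str(h).ljust(w) for h, w in zip(headers, widths)) + " |",
            "| " + " | ".join("-" * w for w in widths) + " |",
        ]
        for row in frame.itertuples(index=False):
            lines.append(
                "| " + " | ".join(str(v).ljust(w) for v, w in zip(row, widths)) + " |"
            )
        return "\n".join(lines) + "\n"
    raise ValueError(f"unknown render format {fmt!r}")


def parse_rendered(text: str, fmt: str = "csv") -> pd.DataFrame:
    """Parse a rendered table back into its cell strings (markers included)."""
    if fmt == "csv":
        rows = list(csv.reader(io.StringIO(text)))
    elif fmt == "markdown":
        raw = [ln for ln in text.splitlines() if ln.strip().startswith("|")]
        rows = [
            [c.strip() for c in ln.strip().strip("|").split("|")] for ln in raw
        ]
        rows = [rows[0]] + rows[2:]  # drop the separator line
    else:
        raise ValueError(f"unknown render format {fmt!r}")
    if not rows:
        return pd.DataFrame()
    return pd.DataFrame(rows[1:], columns=rows[0])
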