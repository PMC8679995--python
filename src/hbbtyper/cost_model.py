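"""Per-sample consumable cost under configurable multiplexing.

Each consumable line is either used once (or a fixed number of times) per
sample, shared across a barcoded library, or shared across a whole
flowcell.  Shared lines amortise with the multiplexing configuration:

* ``per_sample``  — cost = cost_per_reaction × units_per_sample
* ``per_library`` — cost = cost_per_reaction / samples_per_library
* ``per_flowcell``— cost = (cost_per_reaction × reactions_per_item)
                     / (samples_per_library × libraries_per_flowcell)

where for a flowcell line ``reactions_per_item`` is the sample capacity
at which the vendor's per-reaction price is quoted, so its total price is
recovered before amortisation.  Totals are computed from unrounded
fractions and rounded to pennies only for presentation.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd

__all__ = ["CostItem", "MultiplexConfig", "cost_per_sample", "load_cost_table",
           "write_cost_table", "bundled_cost_table_path", "default_cost_items"]

_SHARING = ("per_sample", "per_library", "per_flowcell")


@dataclass(frozen=True)
class CostItem:
    name: str
    reactions_per_item: int
    cost_per_reaction: float
    units_per_sample: float  # consumed only by per_sample lines
    sharing: str = "per_sample"

    def __post_init__(self) -> None:
        if self.cost_per_reaction < 0 or self.reactions_per_item <= 0:
            raise ValueError(f"invalid cost line {self.name!r}")
        if self.units_per_sample <= 0:
            raise ValueError(f"{self.name}: units_per_sample must be > 0")
        if self.sharing not in _SHARING:
            raise ValueError(f"{self.name}: unknown sharing mode {self.sharing!r}")


@dataclass(frozen=True)
class MultiplexConfig:
    samples_per_library: int = 24
    libraries_per_flowcell: int = 8

    def __post_init__(self) -> None:
        if self.samples_per_library < 1 or self.libraries_per_flowcell < 1:
            raise ValueError("multiplex counts must be >= 1")


def item_cost(item: CostItem, config: MultiplexConfig) -> float:
    if item.sharing == "per_sample":
        return item.cost_per_reaction * item.units_per_sample
    if item.sharing == "per_library":
        return item.cost_per_reaction / config.samples_per_library
    total_item_price = item.cost_per_reaction * item.reactions_per_item
    return total_item_price / (
        config.samples_per_library * config.libraries_per_flowcell
    )


def cost_per_sample(
    items: list[CostItem], config: MultiplexConfig = MultiplexConfig()
) -> tuple[float, pd.DataFrame]:
    """Itemised per-sample cost and exact (unrounded) total."""
    if not items:
        raise ValueError("no cost items")
    rows = [
        {"item": it.name, "sharing": it.sharing, "cost_per_sample": item_cost(it, config)}
        for it in items
    ]
    table = pd.DataFrame(rows)
    return float(table["cost_per_sample"].sum()), table


def default_cost_items() -> list[CostItem]:
    """The bundled consumables model for the assay (GBP per line).

    The flowcell line's per-reaction price is quoted at a 192-sample
    capacity (24 samples × 8 flushed libraries).
    """
    return [
        CostItem("QiAmp DNA blood mini kit", 250, 1.86, 1, "per_sample"),
        CostItem("Enrichment Step 1", 200, 0.72, 1, "per_sample"),
        CostItem("Enrichment Step 2", 1000, 0.93, 2, "per_sample"),
        CostItem("Enrichment Step 3", 50, 9.24, 1, "per_library"),
        CostItem("PCR barcoding kit", 960, 1.42, 1, "per_sample"),
        CostItem("Ligation sequencing kit", 6, 80.00, 1, "per_library"),
        CostItem("SpotON flowcell", 192, 1.98, 1, "per_flowcell"),
    ]


_COLUMNS = ["name", "reactions_per_item", "cost_per_reaction", "units_per_sample",
            "sharing"]


def write_cost_table(items: list[CostItem], path: str | Path) -> None:
    df = pd.DataFrame([
        {
            "name": it.name,
            "reactions_per_item": it.reactions_per_item,
            "cost_per_reaction": it.cost_per_reaction,
            "units_per_sample": it.units_per_sample,
            "sharing": it.sharing,
        }
        for it in items
    ])
    df.to_csv(path, sep="\t", index=False)


def load_cost_table(path: str | Path) -> list[CostItem]:
    df = pd.read_csv(path, sep="\t", comment="#")
    if df.empty:
        raise ValueError(f"cost table {path} is empty")
    missing = set(_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"cost table {path} lacks columns {sorted(missing)}")
    items = []
    for _, row in df.iterrows():
        try:
            cpr = float(row["cost_per_reaction"])
        except (TypeError, ValueError) as exc:
            raise ValueError(
                f"cost table {path}: malformed currency {row['cost_per_reaction']!r}"
            ) from exc
        items.append(
            CostItem(
                name=str(row["name"]),
                reactions_per_item=int(row["reactions_per_item"]),
                cost_per_reaction=cpr,
                units_per_sample=float(row["units_per_sample"]),
                sharing=str(row["sharing"]),
            )
        )
    return items


def bundled_cost_table_path() -> Path:
    return Path(resources.files("hbbtyper.data") / "cost_table.tsv")
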