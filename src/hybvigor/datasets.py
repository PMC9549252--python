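"""Published identification counts for the rice trio study.

The numbers below are the printed per-variety identification counts for
an inter-subspecific hybrid rice combination (maternal line Z04A,
paternal line ZHF1015, F1 hybrid ZY19) and the abstract-level
differential-expression totals. They are recorded verbatim so that the
internally recomputable arithmetic — class proportions, per-variety
totals and DE sums — can be re-derived from the raw counts rather than
copied.

All functions recompute; none return hard-coded derived values.
"""

from __future__ import annotations

from .iolib import ConfigError

#: per-variety identification counts, keyed RNA type -> subtype -> counts.
#: Variety order in each tuple: (maternal, hybrid, paternal); "total" is
#: the printed union-level total across the trio.
RICE_TRIO_COUNTS: dict[str, dict[str, dict[str, object]]] = {
    "miRNA": {
        "known miRNA": {"maternal": 471, "hybrid": 472, "paternal": 427,
                        "total": 522},
        "novel miRNA": {"maternal": 343, "hybrid": 345, "paternal": 338,
                        "total": 345},
    },
    "lncRNA": {
        "intronic lncRNA": {"maternal": 164, "hybrid": 185, "paternal": 177,
                            "total": 219},
        "antisense lncRNA": {"maternal": 676, "hybrid": 765, "paternal": 708,
                             "total": 955},
        "sense lncRNA": {"maternal": 238, "hybrid": 243, "paternal": 231,
                         "total": 315},
        "lincRNA": {"maternal": 1113, "hybrid": 1308, "paternal": 1113,
                    "total": 1789},
    },
    "circRNA": {
        "circRNA": {"maternal": 913, "hybrid": 1059, "paternal": 1106,
                    "total": 2521},
    },
    "mRNA": {
        "mRNA": {"maternal": 29903, "hybrid": 30450, "paternal": 29091,
                 "total": 36260},
    },
}

#: differentially-expressed ncRNAs between the hybrid and its parents
#: (DE_HP sets), per RNA class.
RICE_TRIO_DE_HP: dict[str, int] = {
    "miRNA": 169,
    "lncRNA": 573,
    "circRNA": 42,
}


def class_total(rna_type: str, subtype: str) -> int:
    """Printed union-level total for one RNA subtype."""
    try:
        return int(RICE_TRIO_COUNTS[rna_type][subtype]["total"])
    except KeyError as exc:
        raise ConfigError(f"unknown RNA type/subtype: {exc}") from exc


def type_total(rna_type: str) -> int:
    """Union-level total across the subtypes of one RNA type."""
    if rna_type not in RICE_TRIO_COUNTS:
        raise ConfigError(f"unknown RNA type {rna_type!r}")
    return sum(int(v["total"]) for v in RICE_TRIO_COUNTS[rna_type].values())


def class_proportion(rna_type: str, subtype: str, ndigits: int = 2) -> float:
    """Percentage of one subtype within its RNA type, recomputed from the
    printed class counts and rounded to ``ndigits``."""
    return round(100.0 * class_total(rna_type, subtype) / type_total(rna_type),
                 ndigits)


def variety_total(rna_type: str, variety: str) -> int:
    """Per-variety identification total for one RNA type, recomputed by
    summing the printed per-variety class counts."""
    if rna_type not in RICE_TRIO_COUNTS:
        raise ConfigError(f"unknown RNA type {rna_type!r}")
    try:
        return sum(int(v[variety]) for v in RICE_TRIO_COUNTS[rna_type].values())
    except KeyError as exc:
        raise ConfigError(f"unknown variety {variety!r}") from exc


def de_hp_total() -> int:
    """Total differentially expressed ncRNAs in the hybrid (sum over the
    three ncRNA classes)."""
    return sum(RICE_TRIO_DE_HP.values())
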