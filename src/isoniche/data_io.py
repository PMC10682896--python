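"""Reading, writing and summarising isotope tables.

The analysis operates on rectangular tables of individual animals: one row per
individual, a species label, and per-individual stable-isotope values in
delta-notation (per mil, ‰).  The default isotope triplet is
(δ¹³C, δ¹⁵N, δ³⁴S) in that fixed order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: canonical isotope column ordering used throughout the package
DEFAULT_ISOTOPES: tuple[str, ...] = ("d13C", "d15N", "d34S")

#: optional metadata columns recognised by the CSV reader
OPTIONAL_COLUMNS: tuple[str, ...] = ("id", "ccl_cm", "date")


def delta_from_ratio(r_sample, r_standard):
    """Convert raw isotope ratios to delta-notation in per mil (‰).

    delta = (R_sample / R_standard - 1) * 1000, with R_standard the ratio of
    the international reference material (e.g. Vienna PeeDee Belemnite for
    carbon).  Accepts scalars or arrays (broadcast).

    Raises
    ------
    ValueError
        If any standard ratio is not strictly positive, or a sample ratio is
        negative.
    """
    r_sample = np.asarray(r_sample, dtype=float)
    r_standard = np.asarray(r_standard, dtype=float)
    if np.any(r_standard <= 0) or not np.all(np.isfinite(r_standard)):
        raise ValueError("r_standard must be positive and finite")
    if np.any(r_sample < 0):
        raise ValueError("r_sample must be non-negative")
    out = (r_sample / r_standard - 1.0) * 1000.0
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class SpeciesDataset:
    """One species' n x d matrix of isotope values.

    Attributes
    ----------
    species_label : str
        Species code (e.g. ``"Cc"``, ``"Cm"``, ``"Lk"``).
    values : ndarray of shape (n, d)
        Isotope values in ‰, columns ordered as ``isotopes``.
    isotopes : tuple of str
        Declared column ordering.
    """

    species_label: str
    values: np.ndarray
    isotopes: tuple[str, ...] = field(default=DEFAULT_ISOTOPES)

    def __post_init__(self):
        values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if values.shape[0] < 1:
            raise ValueError("dataset needs at least one record")
        if values.shape[1] != len(self.isotopes):
            raise ValueError(
                f"values have {values.shape[1]} columns but "
                f"{len(self.isotopes)} isotopes declared"
            )
        if not np.all(np.isfinite(values)):
            raise ValueError("isotope values must be finite (drop incomplete records)")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "isotopes", tuple(self.isotopes))

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def d(self) -> int:
        return self.values.shape[1]


def read_isotope_csv(path, column_map=None, isotopes=DEFAULT_ISOTOPES):
    """Read an isotope CSV into one :class:`SpeciesDataset` per species.

    The file must have a header row and at minimum a species column plus one
    column per isotope.  ``column_map`` maps the canonical names
    (``"species"``, ``"d13C"``, ...) to the file's actual column names, so
    arbitrarily-named deposits can be read without editing the file.

    Records with any missing or non-numeric isotope value are dropped — the
    niche model is jointly d-variate, so partial records cannot enter the
    covariance estimate.  The drop count is logged and returned.

    Returns
    -------
    datasets : dict[str, SpeciesDataset]
        Keyed by species label, insertion-ordered by first appearance.
    n_dropped : int
        Number of records removed for incomplete isotope values.
    """
    column_map = dict(column_map or {})
    df = pd.read_csv(path)
    required = ["species", *isotopes]
    mapped = {name: column_map.get(name, name) for name in required}
    missing = [col for col in mapped.values() if col not in df.columns]
    if missing:
        raise KeyError(f"missing required column(s) in {path}: {missing}")

    sub = df[[mapped[name] for name in required]].copy()
    sub.columns = required
    for iso in isotopes:
        sub[iso] = pd.to_numeric(sub[iso], errors="coerce")
    complete = sub[list(isotopes)].notna().all(axis=1)
    n_dropped = int((~complete).sum())
    if n_dropped:
        logger.info("dropped %d record(s) with missing isotope values", n_dropped)
    sub = sub[complete]

    datasets: dict[str, SpeciesDataset] = {}
    for label in sub["species"].astype(str).unique():
        block = sub.loc[sub["species"].astype(str) == label, list(isotopes)]
        if block.empty:
            logger.warning("species %s has no complete records; skipped", label)
            continue
        datasets[label] = SpeciesDataset(label, block.to_numpy(float), tuple(isotopes))
    return datasets, n_dropped


def write_isotope_csv(datasets, path, isotopes=None):
    """Write species datasets back to the canonical CSV layout."""
    datasets = list(datasets.values()) if isinstance(datasets, dict) else list(datasets)
    isotopes = tuple(isotopes or datasets[0].isotopes)
    frames = []
    for ds in datasets:
        frame = pd.DataFrame(ds.values, columns=list(isotopes))
        frame.insert(0, "species", ds.species_label)
        frames.append(frame)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def summarize_species(dataset: SpeciesDataset) -> pd.DataFrame:
    """Per-isotope summary statistics for one species.

    Returns one row per isotope with min, max, ``delta_range`` (max - min),
    mean, sample SD (n-1 denominator) and n.  With a single record the SD is
    undefined and reported as NaN, never zero.
    """
    x = dataset.values
    n = dataset.n
    sd = x.std(axis=0, ddof=1) if n >= 2 else np.full(dataset.d, np.nan)
    return pd.DataFrame(
        {
            "species": dataset.species_label,
            "isotope": list(dataset.isotopes),
            "min": x.min(axis=0),
            "max": x.max(axis=0),
            "delta_range": x.max(axis=0) - x.min(axis=0),
            "mean": x.mean(axis=0),
            "sd": sd,
            "n": n,
        }
    )


def summary_table(datasets) -> pd.DataFrame:
    """Stack per-species summaries into one table (species x isotope rows)."""
    datasets = datasets.values() if isinstance(datasets, dict) else datasets
    return pd.concat(
        [summarize_species(ds) for ds in datasets], ignore_index=True
    )
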