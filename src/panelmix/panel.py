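"""Categorical panel data: containers, readers, recoding, and tabulation.

A panel holds integer item responses for N respondents at T occasions on J
items. Category codes are 1-based internally (``1..C_j`` per item); ``0``
marks a missing response. Respondents who miss an entire later occasion
(attrition) are retained — the likelihood machinery marginalizes over them.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError, ValidationError

MISSING = 0

_DEFAULT_NA = {"", "NA", "N/A", "NaN", "nan", "."}


@dataclass
class ResponsePanel:
    """N x T x J categorical responses with optional covariates and grouping.

    Attributes
    ----------
    responses : ndarray of int, shape (N, T, J)
        Category codes ``1..C_j``; ``0`` is missing.
    n_categories : ndarray of int, shape (J,)
        Number of categories per item.
    items : list of str
        Item names, length J.
    ids : ndarray, shape (N,)
        Respondent identifiers (file order preserved).
    covariates : pandas.DataFrame or None
        Numeric respondent-level covariates, aligned with ``ids``.
    group : ndarray or None
        Categorical group label per respondent.
    """

    responses: np.ndarray
    n_categories: np.ndarray
    items: list
    ids: np.ndarray = None
    covariates: pd.DataFrame = None
    group: np.ndarray = None

    def __post_init__(self):
        self.responses = np.asarray(self.responses, dtype=np.int64)
        if self.responses.ndim != 3:
            raise ValidationError("responses must be an (N, T, J) array")
        n, t, j = self.responses.shape
        if min(n, t, j) < 1:
            raise ValidationError("panel requires N >= 1, T >= 1, J >= 1")
        self.n_categories = np.asarray(self.n_categories, dtype=np.int64)
        if self.n_categories.shape != (j,):
            raise ValidationError("n_categories must have one entry per item")
        if np.any(self.n_categories < 1):
            raise ValidationError("every item needs at least one category")
        if len(self.items) != j:
            raise ValidationError("items must name every item column")
        if self.ids is None:
            self.ids = np.arange(n)
        self.ids = np.asarray(self.ids)
        if self.ids.shape[0] != n:
            raise ValidationError("ids must align with respondents")
        bad = (self.responses < 0) | (self.responses > self.n_categories[None, None, :])
        if np.any(bad):
            i, t_, j_ = map(int, np.argwhere(bad)[0])
            raise ValidationError(
                f"response code {self.responses[i, t_, j_]} out of range 1.."
                f"{self.n_categories[j_]} for item {self.items[j_]!r} "
                f"(respondent index {i}, occasion {t_ + 1})"
            )
        if self.covariates is not None and len(self.covariates) != n:
            raise ValidationError("covariates must align with respondents")
        if self.group is not None:
            self.group = np.asarray(self.group)
            if self.group.shape[0] != n:
                raise ValidationError("group labels must align with respondents")

    @property
    def n_respondents(self) -> int:
        return self.responses.shape[0]

    @property
    def n_occasions(self) -> int:
        return self.responses.shape[1]

    @property
    def n_items(self) -> int:
        return self.responses.shape[2]

    def occasion(self, t: int) -> np.ndarray:
        """Responses at 0-based occasion ``t`` as an (N, J) array."""
        return self.responses[:, t, :]


@dataclass
class PatternTable:
    """Distinct observed response vectors with frequencies.

    ``patterns`` has shape (n_patterns, T_scope, J) where ``T_scope`` is 1 for a
    single-occasion table. ``W`` is the number of *possible* complete-response
    cells, ``(prod_j C_j) ** T`` — typically far larger than the number of
    observed patterns.
    """

    patterns: np.ndarray
    frequencies: np.ndarray
    n_categories: np.ndarray
    items: list = field(default_factory=list)
    n_dropped: int = 0

    def __post_init__(self):
        self.patterns = np.asarray(self.patterns, dtype=np.int64)
        self.frequencies = np.asarray(self.frequencies, dtype=np.int64)
        if self.patterns.ndim != 3:
            raise ValidationError("patterns must be (n_patterns, T, J)")
        if self.frequencies.shape != (self.patterns.shape[0],):
            raise ValidationError("one frequency per pattern required")
        if np.any(self.frequencies < 0):
            raise ValidationError("frequencies must be nonnegative")
        self.n_categories = np.asarray(self.n_categories, dtype=np.int64)

    @property
    def n(self) -> int:
        """Total frequency (respondents tabulated)."""
        return int(self.frequencies.sum())

    @property
    def n_patterns(self) -> int:
        return self.patterns.shape[0]

    @property
    def n_occasions(self) -> int:
        return self.patterns.shape[1]

    @property
    def n_items(self) -> int:
        return self.patterns.shape[2]

    @property
    def W(self) -> int:
        """Cell count of the complete contingency table, ``(prod_j C_j)^T``."""
        per_occasion = int(np.prod([int(c) for c in self.n_categories]))
        return per_occasion ** self.patterns.shape[1]

    def to_frame(self) -> pd.DataFrame:
        """Two-column export: pattern string (occasions '|'-separated,
        missing '.') and frequency."""
        rows = []
        for p in self.patterns:
            occ = ["".join("." if c == MISSING else str(int(c)) for c in row) for row in p]
            rows.append("|".join(occ))
        return pd.DataFrame({"pattern": rows, "frequency": self.frequencies})


def _load_layout(layout):
    if isinstance(layout, (str, Path)):
        text = Path(layout).read_text()
        if str(layout).endswith(".json"):
            return json.loads(text)
        return yaml.safe_load(text)
    if isinstance(layout, dict):
        return layout
    raise ConfigurationError("layout must be a dict or a path to YAML/JSON")


def _resolve_columns(layout, columns):
    """Map (item, occasion) -> column name from template or explicit mapping."""
    items = layout.get("items")
    if not items:
        raise ConfigurationError("layout must list 'items'")
    n_occ = int(layout.get("n_occasions", 1))
    explicit = layout.get("columns")
    mapping = {}
    if explicit:
        for col, (item, occ) in explicit.items():
            mapping[(item, int(occ))] = col
    else:
        template = layout.get("column_format", "{item}_t{occ}")
        for item in items:
            for occ in range(1, n_occ + 1):
                if n_occ == 1 and template == "{item}_t{occ}" and item in columns:
                    mapping[(item, occ)] = item
                else:
                    mapping[(item, occ)] = template.format(item=item, occ=occ)
    for key, col in mapping.items():
        if col not in columns:
            raise ConfigurationError(
                f"column {col!r} for item/occasion {key} not found in file"
            )
    return items, n_occ, mapping


def _category_labels(layout, items, values_by_item):
    """Per-item list of raw category labels, ordered; raw labels map to 1..C."""
    spec = layout.get("categories")
    labels = {}
    for j, item in enumerate(items):
        if spec is None:
            labels[item] = sorted(values_by_item[item])
        elif isinstance(spec, int):
            labels[item] = list(range(1, spec + 1))
        elif isinstance(spec, dict):
            labels[item] = list(spec[item])
        else:  # shared list for all items
            labels[item] = list(spec)
    return labels


def read_panel(source, layout) -> ResponsePanel:
    """Read a delimited file (or DataFrame) into a validated :class:`ResponsePanel`.

    ``layout`` (dict or YAML/JSON path) names the structure::

        items: [Physical, Talking, ...]
        n_occasions: 3
        column_format: "{item}_t{occ}"   # or explicit columns: {col: [item, occ]}
        categories: 4                     # or per-item lists of raw labels
        id: student_id                    # optional
        covariates: [grade]               # optional
        group: school_type                # optional
        missing: ["", "NA"]               # optional extra sentinels
        format: wide                      # or "long" with id/occasion/item/value keys

    Raw category labels are normalized to ``1..C`` in declared (or sorted
    observed) order. Respondent order follows file order.
    """
    layout = _load_layout(layout)
    if isinstance(source, pd.DataFrame):
        df = source.copy()
    else:
        df = pd.read_csv(source, sep=layout.get("delimiter", ","), dtype=object,
                         keep_default_na=False)
    na = _DEFAULT_NA | set(map(str, layout.get("missing", [])))

    if layout.get("format", "wide") == "long":
        idc = layout.get("id", "id")
        occ_c = layout.get("occasion", "occasion")
        item_c = layout.get("item", "item")
        val_c = layout.get("value", "value")
        for col in (idc, occ_c, item_c, val_c):
            if col not in df.columns:
                raise ConfigurationError(f"long-format column {col!r} not found")
        keep = [c for c in df.columns if c not in (occ_c, item_c, val_c)]
        wide = df.pivot_table(index=idc, columns=[item_c, occ_c], values=val_c,
                              aggfunc="first", sort=False)
        wide.columns = [f"{i}_t{int(t)}" for i, t in wide.columns]
        extra = df.drop_duplicates(idc).set_index(idc)[[c for c in keep if c != idc]]
        df = wide.join(extra).reset_index()
        layout = dict(layout)
        layout["format"] = "wide"
        layout.setdefault("column_format", "{item}_t{occ}")
        layout["id"] = idc

    items, n_occ, colmap = _resolve_columns(layout, set(df.columns))
    n = len(df)
    if n < 1:
        raise ValidationError("file contains no data rows")

    def cell_value(raw):
        if raw is None or (isinstance(raw, float) and np.isnan(raw)):
            return None
        s = str(raw).strip()
        if s in na:
            return None
        try:
            f = float(s)
            return int(f) if f == int(f) else s
        except ValueError:
            return s

    raw_cells = {}
    values_by_item = {item: set() for item in items}
    for (item, occ), col in colmap.items():
        vals = [cell_value(v) for v in df[col]]
        raw_cells[(item, occ)] = vals
        values_by_item[item].update(v for v in vals if v is not None)

    labels = _category_labels(layout, items, values_by_item)
    n_categories = np.array([len(labels[item]) for item in items])
    code_of = {item: {lab: k + 1 for k, lab in enumerate(labels[item])}
               for item in items}

    responses = np.zeros((n, n_occ, len(items)), dtype=np.int64)
    for (item, occ), vals in raw_cells.items():
        j = items.index(item)
        lut = code_of[item]
        for i, v in enumerate(vals):
            if v is None:
                continue
            if v not in lut:
                raise ValidationError(
                    f"value {v!r} in column {colmap[(item, occ)]!r}, row {i + 2} "
                    f"(1-based with header) is outside the declared categories "
                    f"{labels[item]} for item {item!r}"
                )
            responses[i, occ - 1, j] = lut[v]

    ids = df[layout["id"]].to_numpy() if layout.get("id") in df.columns else np.arange(n)
    cov = None
    cov_cols = layout.get("covariates") or []
    if cov_cols:
        missing_cov = [c for c in cov_cols if c not in df.columns]
        if missing_cov:
            raise ConfigurationError(f"covariate columns not found: {missing_cov}")
        cov = df[cov_cols].apply(pd.to_numeric, errors="coerce").reset_index(drop=True)
    group = None
    if layout.get("group"):
        if layout["group"] not in df.columns:
            raise ConfigurationError(f"group column {layout['group']!r} not found")
        group = df[layout["group"]].to_numpy()

    return ResponsePanel(responses, n_categories, list(items), ids=ids,
                         covariates=cov, group=group)


def write_panel(panel: ResponsePanel, path, column_format="{item}_t{occ}") -> None:
    """Write a panel to wide CSV (missing cells empty); inverse of the default
    wide reader layout."""
    data = {"id": panel.ids}
    for occ in range(1, panel.n_occasions + 1):
        for j, item in enumerate(panel.items):
            col = column_format.format(item=item, occ=occ)
            vals = panel.responses[:, occ - 1, j]
            data[col] = ["" if v == MISSING else str(int(v)) for v in vals]
    out = pd.DataFrame(data)
    if panel.covariates is not None:
        for c in panel.covariates.columns:
            out[c] = panel.covariates[c].to_numpy()
    if panel.group is not None:
        out["group"] = panel.group
    out.to_csv(path, index=False)


def collapse_categories(panel: ResponsePanel, mapping) -> ResponsePanel:
    """Merge response categories per item (e.g. dichotomize a 4-point scale).

    ``mapping`` is either one ``{old: new}`` dict applied to every item or a
    ``{item: {old: new}}`` dict. The map must cover every old category and hit
    every new index ``1..C_new`` (surjection). Missing stays missing.
    """
    if not isinstance(mapping, dict):
        raise ConfigurationError("mapping must be a dict")
    per_item = mapping if all(isinstance(v, dict) for v in mapping.values()) else {
        item: mapping for item in panel.items
    }
    new_resp = panel.responses.copy()
    new_ncat = panel.n_categories.copy()
    for item, m in per_item.items():
        if item not in panel.items:
            raise ConfigurationError(f"unknown item {item!r} in mapping")
        j = panel.items.index(item)
        c_old = int(panel.n_categories[j])
        if set(m.keys()) != set(range(1, c_old + 1)):
            raise ConfigurationError(
                f"mapping for item {item!r} must cover old categories 1..{c_old}"
            )
        new_vals = set(m.values())
        c_new = max(new_vals)
        if new_vals != set(range(1, c_new + 1)):
            raise ConfigurationError(
                f"mapping for item {item!r} must be onto 1..{c_new}"
            )
        lut = np.zeros(c_old + 1, dtype=np.int64)
        for old, new in m.items():
            lut[old] = new
        new_resp[:, :, j] = lut[panel.responses[:, :, j]]
        new_ncat[j] = c_new
    return ResponsePanel(new_resp, new_ncat, list(panel.items), ids=panel.ids,
                         covariates=panel.covariates, group=panel.group)


def marginal_proportions(panel: ResponsePanel) -> pd.DataFrame:
    """Per-item, per-occasion category proportions over non-missing responses.

    Returns a DataFrame indexed by (item, occasion) with one column per
    category code. Item-occasions with no observed responses are NaN and
    flagged with a warning, never silently zero.
    """
    rows = []
    index = []
    c_max = int(panel.n_categories.max())
    for j, item in enumerate(panel.items):
        for t in range(panel.n_occasions):
            col = panel.responses[:, t, j]
            obs = col[col != MISSING]
            index.append((item, t + 1))
            if obs.size == 0:
                warnings.warn(
                    f"item {item!r} has no observed responses at occasion {t + 1}; "
                    "proportions undefined", UserWarning, stacklevel=2)
                rows.append([np.nan] * c_max)
                continue
            counts = np.bincount(obs, minlength=c_max + 1)[1:c_max + 1]
            props = counts / obs.size
            props[int(panel.n_categories[j]):] = np.nan
            rows.append(list(props))
    return pd.DataFrame(
        rows,
        index=pd.MultiIndex.from_tuples(index, names=["item", "occasion"]),
        columns=[f"cat{c}" for c in range(1, c_max + 1)],
    )


def pattern_frequencies(panel: ResponsePanel, scope="joint",
                        drop_empty: bool = True) -> PatternTable:
    """Tabulate distinct observed response vectors.

    ``scope`` is ``"joint"`` (all occasions, vectors of length T*J) or a
    0-based occasion index. Missing markers are preserved, so partially
    observed vectors form their own patterns. With ``drop_empty`` (default),
    respondents with no observed item in scope are excluded from the table and
    counted in ``n_dropped`` — they carry no likelihood information.
    """
    if scope == "joint":
        block = panel.responses
    else:
        t = int(scope)
        if not 0 <= t < panel.n_occasions:
            raise ConfigurationError(f"occasion index {t} out of range")
        block = panel.responses[:, t:t + 1, :]
    flat = block.reshape(block.shape[0], -1)
    n_dropped = 0
    if drop_empty:
        keep = (flat != MISSING).any(axis=1)
        n_dropped = int((~keep).sum())
        flat = flat[keep]
    if flat.shape[0] == 0:
        raise ValidationError("no respondents with observed data in scope")
    uniq, counts = np.unique(flat, axis=0, return_counts=True)
    patterns = uniq.reshape(uniq.shape[0], block.shape[1], block.shape[2])
    return PatternTable(patterns, counts, panel.n_categories,
                        items=list(panel.items), n_dropped=n_dropped)
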