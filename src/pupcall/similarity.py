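"""Gower dissimilarity and Mantel association of call feature tables.

To quantify how closely matched calls resemble the playback template in
multiple parameters at once, calls are described by mixed-type feature
vectors (durations, F0 statistics, peak frequency, inter-call interval,
sequence position), pairwise Gower dissimilarities are computed for the
responses and for the template calls they are aligned to, and the Mantel
statistic (Pearson correlation of the two distance matrices, with a joint
row/column permutation null) measures their structural correspondence.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings
import zlib

import numpy as np
import pandas as pd

from .colony import age_bin
from .stimuli import StimulusTemplate, TEMPLATES, get_template

#: Default per-call feature set (a configurable stand-in for the study's
#: unpublished parameter list).
DEFAULT_FEATURES = (
    "duration_s",
    "mean_f0",
    "min_f0",
    "max_f0",
    "mean_peak",
    "inter_call_interval_s",
    "position",
)
ORDINAL_FEATURES = ("position",)


def gower_matrix(
    table: pd.DataFrame,
    ranges: dict[str, float] | None = None,
    ordinal: tuple[str, ...] = ORDINAL_FEATURES,
) -> np.ndarray:
    """Pairwise Gower dissimilarities of a mixed-type feature table.

    Per variable, dissimilarity is ``|x_i - x_j| / range``; ordinal
    variables are converted to ranks first. Entries are averaged over the
    variables available in both rows (missing values are ignored
    pairwise). Zero-range variables are dropped with a warning.

    Parameters
    ----------
    table
        One row per object, numeric columns (NaN = missing).
    ranges
        Optional per-variable normalization spans; computed over the table
        where not given.

    Returns
    -------
    (n, n) symmetric float array with zero diagonal, entries in [0, 1].
    """
    if len(table) < 2:
        raise ValueError("need at least two objects")
    cols = list(table.columns)
    X = np.empty((len(table), len(cols)))
    spans = np.empty(len(cols))
    keep = []
    for j, c in enumerate(cols):
        x = table[c].to_numpy(dtype=float)
        if np.all(np.isnan(x)):
            raise ValueError(f"variable {c!r} is entirely missing")
        if c in ordinal:
            x = pd.Series(x).rank(na_option="keep").to_numpy()
        span = (
            ranges[c]
            if ranges is not None and c in ranges
            else np.nanmax(x) - np.nanmin(x)
        )
        if span <= 0:
            warnings.warn(f"variable {c!r} has zero range; dropped", stacklevel=2)
            continue
        X[:, len(keep)] = x
        spans[len(keep)] = span
        keep.append(c)
    if not keep:
        raise ValueError("no usable variables (all constant or missing)")
    X = X[:, : len(keep)] / spans[: len(keep)]
    diff = np.abs(X[:, None, :] - X[None, :, :])
    avail = ~np.isnan(diff)
    n_avail = avail.sum(axis=2)
    if np.any(n_avail[~np.eye(len(table), dtype=bool)] == 0):
        raise ValueError("some object pairs share no available variables")
    d = np.where(avail, diff, 0.0).sum(axis=2) / np.maximum(n_avail, 1)
    np.fill_diagonal(d, 0.0)
    return np.clip(d, 0.0, 1.0)


@dataclass(frozen=True)
class MantelResult:
    """Mantel statistic with its permutation p-value."""

    r: float
    p_value: float
    n_perm: int
    n_objects: int


def _check_square(m: np.ndarray, name: str) -> np.ndarray:
    m = np.asarray(m, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError(f"{name} must be square")
    if not np.allclose(m, m.T):
        raise ValueError(f"{name} must be symmetric")
    return m


def mantel(
    m_a: np.ndarray,
    m_b: np.ndarray,
    n_perm: int = 9_999,
    seed: int | None = None,
) -> MantelResult:
    """Mantel test between two dissimilarity matrices.

    ``r`` is the Pearson correlation over the n(n-1)/2 upper-triangle
    pairs. The one-sided (greater) p-value permutes rows and columns of
    ``m_b`` jointly: ``p = (1 + #{r_perm >= r_obs}) / (1 + n_perm)``.
    """
    m_a = _check_square(m_a, "m_a")
    m_b = _check_square(m_b, "m_b")
    n = m_a.shape[0]
    if m_b.shape[0] != n:
        raise ValueError("matrix sizes differ")
    if n < 3:
        raise ValueError("need at least 3 objects")
    iu = np.triu_indices(n, k=1)
    a = m_a[iu]
    b = m_b[iu]
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("constant dissimilarity matrix: Mantel r undefined")
    az = (a - a.mean()) / a.std()
    bz = (b - b.mean()) / b.std()
    r_obs = float(np.mean(az * bz))
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        bp = m_b[np.ix_(perm, perm)][iu]
        s = bp.std()
        r_perm = np.mean((bp - bp.mean()) / s * az) if s > 0 else 0.0
        if r_perm >= r_obs - 1e-12:
            count += 1
    return MantelResult(
        r=r_obs, p_value=(1 + count) / (1 + n_perm), n_perm=n_perm, n_objects=n
    )


def template_feature_table(template: StimulusTemplate | str) -> pd.DataFrame:
    """Feature vectors of the template calls themselves.

    Template calls are constant-pitch tonal calls, so their F0 statistics
    and peak frequency all equal the nominal per-call peak frequency.
    """
    if isinstance(template, str):
        template = get_template(template)
    rows = []
    for pos, f in enumerate(template.call_peak_freqs):
        rows.append(
            {
                "duration_s": template.call_duration,
                "mean_f0": f,
                "min_f0": f,
                "max_f0": f,
                "mean_peak": f,
                # onset-to-onset spacing, the same convention used for
                # response calls (missing for the sequence-initial call)
                "inter_call_interval_s": (
                    np.nan
                    if pos == 0
                    else template.call_duration + template.inter_call_interval
                ),
                "position": pos,
            }
        )
    return pd.DataFrame(rows, columns=list(DEFAULT_FEATURES))


def response_feature_table(
    calls: pd.DataFrame, features: tuple[str, ...] = DEFAULT_FEATURES
) -> pd.DataFrame:
    """Select/validate the feature columns of matched response calls."""
    missing = [f for f in features if f not in calls.columns]
    if missing:
        raise ValueError(f"feature columns missing from table: {missing}")
    return calls[list(features)].reset_index(drop=True)


def session_similarity(
    matched_calls: pd.DataFrame,
    template: StimulusTemplate | str | None = None,
    n_perm: int = 9_999,
    seed: int | None = None,
    min_calls: int = 3,
    features: tuple[str, ...] = DEFAULT_FEATURES,
) -> pd.DataFrame:
    """Per pup x age-bin Mantel correlation between responses and template.

    Parameters
    ----------
    matched_calls
        One row per matched response call with the feature columns plus
        ``pup_id``, ``age_days`` and ``position`` (the template call the
        response is aligned to).
    template
        The pup's assigned stimulus template. If None, each row must carry
        a ``window_template`` column naming the template its matched
        window realized (the case for control pups, whose chance matches
        can realize any of the three templates).

    Returns
    -------
    DataFrame
        Columns (pup_id, age_bin, r, p, n_objects, n_perm). Bins with
        fewer than ``min_calls`` matched calls are skipped.

    Notes
    -----
    The template-side matrix is built by position-aligning each response
    call to its template call, so both Gower matrices live on the same
    object set; both use normalization spans pooled over responses and
    template calls so the two matrices share one scale.
    """
    if isinstance(template, str):
        template = get_template(template)
    if template is None and "window_template" not in matched_calls.columns:
        raise ValueError("need a template or a window_template column")
    t_tables = {tid: template_feature_table(tid) for tid in TEMPLATES}
    out = []
    df = matched_calls.copy()
    df["age_bin"] = age_bin(df["age_days"].to_numpy())
    for (pup_id, bin_id), grp in df.groupby(["pup_id", "age_bin"], sort=True):
        if len(grp) < min_calls:
            continue
        resp = response_feature_table(grp, features)
        if template is not None:
            tids = [template.template_id] * len(grp)
        else:
            tids = list(grp["window_template"])
        positions = grp["position"].to_numpy(int)
        aligned = pd.DataFrame(
            [
                t_tables[tid].iloc[min(pos, len(t_tables[tid]) - 1)]
                for tid, pos in zip(tids, positions)
            ]
        ).reset_index(drop=True)
        # pooled spans so both matrices share one scale; position (an
        # integer code in both tables) is compared numerically here
        pooled = pd.concat([resp, aligned[list(features)]], ignore_index=True)
        ranges = {
            c: float(
                np.nanmax(pooled[c].to_numpy(float))
                - np.nanmin(pooled[c].to_numpy(float))
            )
            for c in features
        }
        try:
            m_a = gower_matrix(resp, ranges=ranges, ordinal=())
            m_b = gower_matrix(aligned[list(features)], ranges=ranges, ordinal=())
            child_seed = None
            if seed is not None:
                child_seed = int(
                    np.random.SeedSequence(
                        [seed, zlib.crc32(str(pup_id).encode()), int(bin_id)]
                    ).generate_state(1)[0] % (2**31)
                )
            res = mantel(m_a, m_b, n_perm=n_perm, seed=child_seed)
        except ValueError:
            continue  # degenerate bin (e.g. all responses identical)
        out.append(
            {
                "pup_id": pup_id,
                "age_bin": int(bin_id),
                "r": res.r,
                "p": res.p_value,
                "n_objects": res.n_objects,
                "n_perm": res.n_perm,
            }
        )
    return pd.DataFrame(
        out, columns=["pup_id", "age_bin", "r", "p", "n_objects", "n_perm"]
    )
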