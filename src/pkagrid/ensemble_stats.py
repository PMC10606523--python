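"""Fluctuation statistics of pKa energy components over structure snapshots.

A FrameLedger collects per-frame energy ledgers computed on trajectory
snapshots (e.g. 200 frames at 1 ns stride).  A site's per-frame total shift
is the sum of its dielectric-response and background components plus the
pairwise couplings that exceed a 0.5 pKa-unit threshold; the standard
deviation of that total over frames is the structural-fluctuation
uncertainty, and the pKa reported for the ensemble comes from titrating the
frame-averaged components with an SD/sqrt(N_eff) error bar
(autocorrelation-corrected effective frame count).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .pka_engine import EnergyLedger, EngineSettings, compute_ledger, build_microstate_model
from .dielectric_model import DielectricScene, GridSpec
from .structure_io import ParameterizedStructure, TitratableSite, SitePolicy, find_titratable_sites
from .titration import titrate_exact, titrate_mc, TitrationError, EXACT_SITE_LIMIT

__all__ = [
    "FrameLedger",
    "UncertaintyReport",
    "PAIR_THRESHOLD",
    "per_frame_components",
    "fluctuation_sd",
    "averaged_pka",
    "effective_sample_size",
]

#: pairwise couplings below this magnitude (pKa units) are excluded from the
#: per-frame component totals used in the fluctuation analysis
PAIR_THRESHOLD = 0.5


@dataclass
class FrameLedger:
    frames: list[EnergyLedger]
    pair_threshold: float = PAIR_THRESHOLD
    sites: list[TitratableSite] | None = None

    def __post_init__(self):
        if not self.frames:
            raise ValueError("FrameLedger needs at least one frame")
        ids0 = self.frames[0].site_ids
        for f in self.frames:
            if f.site_ids != ids0:
                raise ValueError(f"frame {f.frame_id}: site list differs from first frame")
        fids = [f.frame_id for f in self.frames]
        if any(b <= a for a, b in zip(fids, fids[1:])):
            raise ValueError("frame_ids must be strictly increasing")

    @property
    def site_ids(self) -> list[str]:
        return self.frames[0].site_ids

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def component_series(self) -> pd.DataFrame:
        """Tidy per-frame, per-site component table."""
        rows = []
        for f in self.frames:
            inter = self._interaction_totals(f)
            for i, sid in enumerate(f.site_ids):
                rows.append({
                    "frame_id": f.frame_id,
                    "site_id": sid,
                    "born_shift": f.born_shift[i],
                    "background_shift": f.background_shift[i],
                    "interaction_total": inter[i],
                    "total_shift": f.born_shift[i] + f.background_shift[i] + inter[i],
                })
        return pd.DataFrame(rows)

    def _interaction_totals(self, ledger: EnergyLedger) -> np.ndarray:
        """Thresholded pairwise contribution to each site's total shift.

        Neighbours enter in their charged reference states: an acid
        neighbour weights its coupling by -1, a base by +1, and the pKa
        shift of site i is minus that interaction energy.  Pairs with
        |W| below the threshold are excluded.
        """
        W = np.where(np.abs(ledger.W) >= self.pair_threshold, ledger.W, 0.0)
        if self.sites is not None:
            c = np.array([-1.0 if s.acid_or_base == "acid" else 1.0 for s in self.sites])
        else:
            c = np.ones(len(ledger.site_ids))
        return -(W @ c)

    def total_shift_matrix(self) -> np.ndarray:
        """(n_frames, n_sites) per-frame total shifts."""
        out = np.empty((self.n_frames, len(self.site_ids)))
        for k, f in enumerate(self.frames):
            out[k] = f.born_shift + f.background_shift + self._interaction_totals(f)
        return out

    def thresholded_pairs(self) -> list[tuple[str, str, float]]:
        """Pairs whose frame-mean |W| reaches the threshold."""
        Wmean = np.mean([f.W for f in self.frames], axis=0)
        ids = self.site_ids
        out = []
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                if abs(Wmean[i, j]) >= self.pair_threshold:
                    out.append((ids[i], ids[j], float(Wmean[i, j])))
        return out


@dataclass
class UncertaintyReport:
    site_ids: list[str]
    mean_total_shift: np.ndarray
    sd_total_shift: np.ndarray
    median_sd: float
    subset: list[str] | None = None
    thresholded_pairs: list = field(default_factory=list)
    averaged_pka: np.ndarray | None = None
    pka_uncertainty: np.ndarray | None = None
    n_frames: int = 0

    def to_frame(self) -> pd.DataFrame:
        data = {
            "site_id": self.site_ids,
            "mean_total_shift": np.round(self.mean_total_shift, 2),
            "sd_total_shift": np.round(self.sd_total_shift, 2),
        }
        if self.averaged_pka is not None:
            data["pka"] = np.round(self.averaged_pka, 2)
            data["pka_uncertainty"] = np.round(self.pka_uncertainty, 2)
        return pd.DataFrame(data)


def per_frame_components(
    frames: Sequence[ParameterizedStructure],
    grid: GridSpec,
    scene_template: DielectricScene,
    policy: SitePolicy | None = None,
    settings: EngineSettings | None = None,
    pair_threshold: float = PAIR_THRESHOLD,
) -> FrameLedger:
    """Run the full energy decomposition on every frame.

    All frames must present the same residue content; the grid is shared so
    per-frame energies are directly comparable.
    """
    from dataclasses import replace

    settings = settings or EngineSettings()
    ledgers = []
    sites0: list[TitratableSite] | None = None
    for frame in frames:
        scene = replace(scene_template, structure=frame)
        dmap = scene.rasterize(grid)
        sites = find_titratable_sites(frame, policy)
        if sites0 is None:
            sites0 = sites
        elif [s.site_id for s in sites] != [s.site_id for s in sites0]:
            raise ValueError(f"frame {frame.frame_id}: site list differs")
        ledgers.append(compute_ledger(frame, sites, dmap, settings, frame_id=frame.frame_id))
    return FrameLedger(frames=ledgers, pair_threshold=pair_threshold, sites=sites0)


def effective_sample_size(series: np.ndarray) -> float:
    """N / (1 + 2 sum of initial positive autocorrelations)."""
    x = np.asarray(series, dtype=float)
    n = len(x)
    if n < 2:
        return float(n)
    x = x - x.mean()
    var = float(np.dot(x, x))
    if var == 0:
        return float(n)
    tau = 0.0
    for lag in range(1, n // 2):
        rho = float(np.dot(x[:-lag], x[lag:])) / var
        if rho <= 0:
            break
        tau += rho
    return n / (1.0 + 2.0 * tau)


def fluctuation_sd(
    ledger: FrameLedger, subset: Sequence[str] | None = None
) -> UncertaintyReport:
    """Sample SD of the per-frame total shift per site; median over ``subset``
    (e.g. the lumen-exposed residues) or over all sites."""
    if ledger.n_frames < 2:
        raise ValueError("fluctuation SD needs at least 2 frames")
    totals = ledger.total_shift_matrix()
    mean = totals.mean(axis=0)
    sd = totals.std(axis=0, ddof=1)
    ids = ledger.site_ids
    if subset is not None:
        missing = set(subset) - set(ids)
        if missing:
            raise ValueError(f"subset sites not in ledger: {sorted(missing)}")
        sel = [ids.index(s) for s in subset]
    else:
        sel = list(range(len(ids)))
    return UncertaintyReport(
        site_ids=ids,
        mean_total_shift=mean,
        sd_total_shift=sd,
        median_sd=float(np.median(sd[sel])),
        subset=list(subset) if subset is not None else None,
        thresholded_pairs=ledger.thresholded_pairs(),
        n_frames=ledger.n_frames,
    )


def averaged_pka(
    ledger: FrameLedger,
    subset: Sequence[str] | None = None,
    ph_grid=None,
    method: str = "auto",
    mc_seed: int = 0,
    order: str = "average-components",
) -> UncertaintyReport:
    """Titration on frame-averaged components with SE-of-mean uncertainty.

    ``order='average-components'`` (default) averages born/background/W over
    frames and titrates once; ``order='average-pka'`` titrates every frame
    and averages the per-frame pKas.  The uncertainty is SD/sqrt(N_eff) of
    the per-frame total shift, with N_eff from the autocorrelation of the
    series; a single frame yields NaN uncertainty (flagged, not an error).
    """
    if ledger.sites is None:
        raise ValueError("ledger must carry its TitratableSite list to titrate")
    report = (
        fluctuation_sd(ledger, subset)
        if ledger.n_frames >= 2
        else UncertaintyReport(
            site_ids=ledger.site_ids,
            mean_total_shift=ledger.total_shift_matrix()[0],
            sd_total_shift=np.full(len(ledger.site_ids), np.nan),
            median_sd=float("nan"),
            thresholded_pairs=ledger.thresholded_pairs(),
            n_frames=1,
        )
    )
    totals = ledger.total_shift_matrix()

    def titrate(model):
        n = model.n_sites
        if method == "mc" or (method == "auto" and n > EXACT_SITE_LIMIT):
            return titrate_mc(model, seed=mc_seed)
        return titrate_exact(model)

    if order == "average-components":
        mean_ledger = EnergyLedger(
            site_ids=ledger.site_ids,
            model_pka=ledger.frames[0].model_pka,
            born_shift=np.mean([f.born_shift for f in ledger.frames], axis=0),
            background_shift=np.mean([f.background_shift for f in ledger.frames], axis=0),
            W=np.mean([f.W for f in ledger.frames], axis=0),
        )
        result = titrate(build_microstate_model(mean_ledger, ledger.sites, ph_grid))
        pkas = np.array([_safe_pka(result, i) for i in range(len(ledger.site_ids))])
    elif order == "average-pka":
        per_frame = []
        for f in ledger.frames:
            result = titrate(build_microstate_model(f, ledger.sites, ph_grid))
            per_frame.append([_safe_pka(result, i) for i in range(len(f.site_ids))])
        pkas = np.nanmean(np.asarray(per_frame, dtype=float), axis=0)
    else:
        raise ValueError(f"unknown averaging order {order!r}")

    if ledger.n_frames >= 2:
        unc = np.array([
            totals[:, i].std(ddof=1) / np.sqrt(effective_sample_size(totals[:, i]))
            for i in range(totals.shape[1])
        ])
    else:
        unc = np.full(len(ledger.site_ids), np.nan)
    report.averaged_pka = pkas
    report.pka_uncertainty = unc
    return report


def _safe_pka(result, i: int) -> float:
    try:
        return result.pka(i)
    except TitrationError:
        return float("nan")
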