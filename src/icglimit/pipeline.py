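"""Run configuration and pipeline orchestration.

One YAML config drives everything: the Monte Carlo grid sweep over
(mu_a, mu_s') pairs, background separation of a measured (or synthetic)
signal table, and the SBR / detection-limit analysis.  Outputs are CSV tables
with a comment header carrying the config hash and master seed, so a rerun
with the same config is byte-identical; absorbed-energy maps can optionally
be persisted to HDF5 keyed by scenario id.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .background_separation import separate_table
from .mc_excitation import GridSpec, OpticalMedium, simulate_excitation
from .mc_emission import (
    Fluorophore,
    build_source_map,
    propagate_emission,
)
from .sbr_sensitivity import (
    FilterSet,
    TissueScenario,
    nmin_curve,
    sbr_concentration_curve,
)

log = logging.getLogger("icglimit")

#: Default (mu_a, mu_s') sweep of the full simulation matrix (1/cm).
DEFAULT_MU_A_GRID = (0.01, 0.02, 0.04, 0.08, 0.16, 0.32, 0.54, 1.28)
DEFAULT_MU_S_REDUCED_GRID = (5.0, 10.0, 20.0, 40.0, 80.0, 160.0)


@dataclass
class RunConfig:
    """Everything needed to reproduce one pipeline run."""

    seed: int = 1
    photons_excitation: int = 1_000_000
    photons_emission: int = 1_000_000
    mu_a_values: tuple[float, ...] = DEFAULT_MU_A_GRID
    mu_s_reduced_values: tuple[float, ...] = DEFAULT_MU_S_REDUCED_GRID
    g: float = 0.9
    n_rel: float = 1.4
    depth: float = 4.0
    radius: float = 2.0
    dr: float = 0.01
    dz: float = 0.01
    platform_radius: float = 1.2
    beam_radius: float = 0.0
    reference_mu_a: float = 0.02
    reference_mu_s_reduced: float = 20.0
    reference_concentration: float = 6.5e-10
    reference_epsilon: float = 180_000.0
    reference_qy: float = 0.02
    tissue_mu_a: float = 0.40
    tissue_mu_s_reduced: float = 15.0
    tissue_epsilon: float = 180_000.0
    tissue_qy: float = 0.13
    epsilon_interval: tuple[float, float] = (150_000.0, 220_000.0)
    qy_interval: tuple[float, float] = (0.12, 0.14)
    af_ref_ratio: float = 0.16
    t_em: float = 0.28
    od_ex: float = 9.2
    od_sweep: tuple[float, float, float] = (6.0, 14.0, 0.25)
    concentration_sweep: tuple[float, ...] = (6.5e-11, 6.5e-10, 6.5e-9, 6.5e-8)
    save_absorption_maps: bool = False

    # -- serialization ------------------------------------------------------

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key, value in data.items():
            if isinstance(value, list):
                data[key] = tuple(value)
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in asdict(self).items()
        }
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))

    @property
    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=list)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    # -- derived objects ----------------------------------------------------

    def medium(self, mu_a: float, mu_s_reduced: float) -> OpticalMedium:
        return OpticalMedium(
            mu_a=mu_a, mu_s_reduced=mu_s_reduced, g=self.g, n_rel=self.n_rel,
            depth=self.depth, radius=self.radius,
        )

    @property
    def grid(self) -> GridSpec:
        return GridSpec(
            dr=self.dr, dz=self.dz,
            nr=int(np.ceil(self.radius / self.dr)),
            nz=int(np.ceil(self.depth / self.dz)),
            platform_radius=self.platform_radius,
        )

    @property
    def reference_medium(self) -> OpticalMedium:
        return self.medium(self.reference_mu_a, self.reference_mu_s_reduced)

    @property
    def tissue_medium(self) -> OpticalMedium:
        return self.medium(self.tissue_mu_a, self.tissue_mu_s_reduced)

    @property
    def reference_fluorophore(self) -> Fluorophore:
        return Fluorophore(
            concentration=self.reference_concentration,
            epsilon=self.reference_epsilon,
            qy=self.reference_qy,
        )

    @property
    def tissue_fluorophore(self) -> Fluorophore:
        return Fluorophore(
            concentration=self.reference_concentration,
            epsilon=self.tissue_epsilon,
            qy=self.tissue_qy,
        )

    @property
    def filters(self) -> FilterSet:
        return FilterSet(t_em=self.t_em, od_ex=self.od_ex)

    def scenario(self, af_ref_ratio: float | None = None) -> TissueScenario:
        return TissueScenario(
            medium=self.tissue_medium,
            fluorophore=self.tissue_fluorophore,
            epsilon_interval=self.epsilon_interval,
            qy_interval=self.qy_interval,
            af_ref_ratio=self.af_ref_ratio if af_ref_ratio is None else af_ref_ratio,
            reference_medium=self.reference_medium,
            reference_fluorophore=self.reference_fluorophore,
        )

    def od_values(self) -> np.ndarray:
        start, stop, step = self.od_sweep
        return np.arange(start, stop + 1e-9, step)

    def pair_list(self) -> list[tuple[float, float]]:
        """All (mu_a, mu_s') pairs to simulate, always including the
        reference and tissue media."""
        pairs = [(a, s) for a in self.mu_a_values for s in self.mu_s_reduced_values]
        for extra in (
            (self.reference_mu_a, self.reference_mu_s_reduced),
            (self.tissue_mu_a, self.tissue_mu_s_reduced),
        ):
            if not any(np.isclose(extra, p).all() for p in pairs):
                pairs.append(extra)
        return pairs


def _write_csv(df: pd.DataFrame, path: Path, config: RunConfig) -> None:
    header = f"# icglimit config={config.config_hash} seed={config.seed}\n"
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, index=False)


def run_grid(
    config: RunConfig,
    out_dir: str | Path,
    resume: bool = True,
) -> pd.DataFrame:
    """Simulate the full (mu_a, mu_s') matrix: one CSV row per pair.

    Per-pair seeds derive from the master seed and the pair's position in the
    full list, so partial (resumed) runs produce the same rows as a fresh
    one.  With ``resume`` (default) pairs already present in the output CSV
    are skipped.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    csv_path = out_dir / "mc_grid.csv"
    existing = None
    if resume and csv_path.exists():
        # round_trip parsing keeps resumed rows bit-identical to the originals
        existing = pd.read_csv(csv_path, comment="#", float_precision="round_trip")
    pairs = config.pair_list()
    grid = config.grid
    fluor = config.reference_fluorophore
    h5 = None
    if config.save_absorption_maps:
        import h5py

        h5 = h5py.File(out_dir / "absorption_maps.h5", "a")
    rows = []
    try:
        for i, (mu_a, mu_sr) in enumerate(pairs):
            if existing is not None and (
                np.isclose(existing["mu_a"], mu_a)
                & np.isclose(existing["mu_s_reduced"], mu_sr)
            ).any():
                row = existing[
                    np.isclose(existing["mu_a"], mu_a)
                    & np.isclose(existing["mu_s_reduced"], mu_sr)
                ].iloc[0]
                rows.append(row.to_dict())
                log.debug("skip (resumed): mu_a=%g mu_s'=%g", mu_a, mu_sr)
                continue
            seed_exc, seed_em = (
                np.random.SeedSequence([config.seed, i]).generate_state(2) % (2**31)
            )
            medium = config.medium(mu_a, mu_sr)
            exc = simulate_excitation(
                medium, grid, config.photons_excitation, int(seed_exc),
                beam_radius=config.beam_radius,
            )
            src = build_source_map(exc.absorption_map, fluor, medium)
            em = propagate_emission(
                src, medium, grid, config.photons_emission, int(seed_em),
                excitation=exc,
            )
            log.info(
                "pair mu_a=%g mu_s'=%g: Rd=%.4g Rf=%.4g Rf/Rd=%.4g",
                mu_a, mu_sr, exc.rd_platform, em.rf_platform, em.ratio_rf_rd,
            )
            if h5 is not None:
                key = f"mu_a={mu_a:g}_mu_s_reduced={mu_sr:g}"
                if key in h5:
                    del h5[key]
                ds = h5.create_dataset(key, data=exc.absorption_map.a)
                ds.attrs["seed"] = int(seed_exc)
            rows.append(
                {
                    "mu_a": mu_a,
                    "mu_s_reduced": mu_sr,
                    "g": config.g,
                    "n_rel": config.n_rel,
                    "rd_platform": exc.rd_platform,
                    "rd_stderr": exc.rd_stderr,
                    "rd_total": exc.rd_total,
                    "rf_platform": em.rf_platform,
                    "rf_stderr": em.rf_stderr,
                    "ratio_rf_rd": em.ratio_rf_rd,
                    "n_photons_excitation": config.photons_excitation,
                    "n_photons_emission": config.photons_emission,
                    "seed_excitation": int(seed_exc),
                    "seed_emission": int(seed_em),
                }
            )
    finally:
        if h5 is not None:
            h5.close()
    table = pd.DataFrame(rows)
    # resumed rows pass through a mixed-dtype Series; restore integer columns
    for col in ("n_photons_excitation", "n_photons_emission",
                "seed_excitation", "seed_emission"):
        table[col] = table[col].round().astype(np.int64)
    _write_csv(table, csv_path, config)
    return table


def run_sensitivity(
    config: RunConfig,
    grid_table: pd.DataFrame,
    separation_table: pd.DataFrame | None = None,
    out_dir: str | Path | None = None,
) -> dict[str, pd.DataFrame]:
    """SBR and detection-limit analysis from a completed MC grid.

    If a separated background table is given, the measured ``Saf/Sf0`` at the
    excitation wavelength closest to 785 nm overrides the configured
    ``af_ref_ratio``.  Writes ``sbr_curve.csv`` and ``nmin_vs_od.csv`` when
    ``out_dir`` is set.
    """
    af_ratio = None
    if separation_table is not None:
        if "s_af" not in separation_table.columns:
            separation_table = separate_table(separation_table)
        idx = (separation_table["wavelength_nm"] - 785.0).abs().idxmin()
        row = separation_table.loc[idx]
        if "s_f0" not in separation_table.columns or pd.isna(row["s_f0"]):
            raise ValueError("separation table lacks the reference signal s_f0")
        af_ratio = float(row["s_af"]) / float(row["s_f0"])
        log.info("using measured Saf/Sf0 = %.4g at %g nm", af_ratio, row["wavelength_nm"])
    scenario = config.scenario(af_ref_ratio=af_ratio)
    sens = nmin_curve(
        scenario, config.filters, od_values=config.od_values(),
        rf_rd_source=grid_table,
    )
    sbr = sbr_concentration_curve(
        config.concentration_sweep,
        sens.saf_over_sf,
        sens.ssc_over_sf,
        scenario.fluorophore.concentration,
    )
    summary = pd.DataFrame(
        [
            {
                "ssc_over_sf": sens.ssc_over_sf,
                "saf_over_sf": sens.saf_over_sf,
                "sbr_at_n0": sens.sbr,
                "nmin": sens.nmin,
                "nmin_low": sens.nmin_band[0],
                "nmin_high": sens.nmin_band[1],
                "nmin_floor": sens.nmin_floor,
                "af_ref_ratio": scenario.af_ref_ratio,
            }
        ]
    )
    tables = {"sbr_curve": sbr, "nmin_vs_od": sens.od_curve, "summary": summary}
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for name, df in tables.items():
            _write_csv(df, out_dir / f"{name}.csv", config)
    return tables
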