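"""Readers, writers, configuration and the end-to-end pipeline.

Conventions: trace CSVs are two columns (time_ns, twist_deg); segment CSVs
carry (start_frame, end_frame, mean_deg, sigma_deg, lifetime_ns); catalogs
add source and cluster columns.  PDB coordinates are angstrom, lattice specs
nm; synthetic trajectories are written as multi-MODEL PDB (one MODEL per
frame, chains A/B for the two protofilaments, one residue per pair) and as a
plain JSON + CSV coordinate table.  Every pipeline run emits a manifest with
the config snapshot, a config hash embedded in all outputs, and per-file
SHA-256 hashes, so reruns with the same seed are byte-identical in their
numeric outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
import urllib.request
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .geometry import (
    BendTrace,
    FilamentTrajectory,
    TwistTrace,
    frame_convention_sensitivity,
    middle_doublet_twist,
)
from .sasa import VDW_RADII, ToyStructure
from .segmentation import SegmentationParams, StateSegment, detect_states
from .state_analysis import (
    StateCatalog,
    cluster_state_means,
    moduli_for_catalog,
    select_n_clusters,
)
from .synthetic_data import gen_twist_trace, preset_schedule

logger = logging.getLogger("filatwist")

__all__ = [
    "read_trace_csv",
    "write_trace_csv",
    "write_bend_csv",
    "read_bend_csv",
    "write_segments_csv",
    "read_segments_csv",
    "write_catalog_csv",
    "read_catalog_csv",
    "write_moduli_csv",
    "read_structure",
    "write_filament_pdb",
    "read_filament_pdb",
    "write_filament_table",
    "read_filament_table",
    "fetch_pdb",
    "PipelineConfig",
    "RunManifest",
    "run_pipeline",
    "MREB_SUBDOMAINS",
]

_FLOAT_FMT = "%.17g"  # full double precision for lossless CSV round-trips

#: Subdomain residue ranges of the MreB fold (actin-like four-domain core),
#: used to place orientation reference points on PDB-derived subunits.
MREB_SUBDOMAINS: dict[str, tuple[tuple[int, int], ...]] = {
    "IA": ((9, 36), (322, 345)),
    "IB": ((37, 81),),
    "IIA": ((151, 186), (265, 321)),
    "IIB": ((187, 264),),
}


# ---------------------------------------------------------------------------
# CSV artifacts


def write_trace_csv(trace: TwistTrace, path) -> None:
    pd.DataFrame({"time_ns": trace.time, "twist_deg": trace.twist}).to_csv(
        path, index=False, float_format=_FLOAT_FMT
    )


def read_trace_csv(path, metadata: dict | None = None) -> TwistTrace:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = {"time_ns", "twist_deg"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing trace columns {sorted(missing)}")
    meta = {"source": str(path)}
    meta.update(metadata or {})
    return TwistTrace(
        time=df["time_ns"].to_numpy(), twist=df["twist_deg"].to_numpy(), metadata=meta
    )


def write_bend_csv(bend: BendTrace, path) -> None:
    pd.DataFrame(
        {
            "time_ns": bend.time,
            "in_plane_deg": bend.in_plane,
            "out_of_plane_deg": bend.out_of_plane,
        }
    ).to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_bend_csv(path) -> BendTrace:
    df = pd.read_csv(path, float_precision="round_trip")
    return BendTrace(
        time=df["time_ns"].to_numpy(),
        in_plane=df["in_plane_deg"].to_numpy(),
        out_of_plane=df["out_of_plane_deg"].to_numpy(),
    )


def _segments_frame(segments: list[StateSegment]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "start_frame": [s.start_frame for s in segments],
            "end_frame": [s.end_frame for s in segments],
            "mean_deg": [s.mean_twist for s in segments],
            "sigma_deg": [s.sigma for s in segments],
            "lifetime_ns": [s.lifetime_ns for s in segments],
        }
    )


def write_segments_csv(segments: list[StateSegment], path) -> None:
    _segments_frame(segments).to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_segments_csv(path) -> list[StateSegment]:
    df = pd.read_csv(path, float_precision="round_trip")
    return [
        StateSegment(
            start_frame=int(r.start_frame),
            end_frame=int(r.end_frame),
            mean_twist=float(r.mean_deg),
            sigma=float(r.sigma_deg),
            lifetime_ns=float(r.lifetime_ns),
        )
        for r in df.itertuples()
    ]


def write_catalog_csv(catalog: StateCatalog, path) -> None:
    df = _segments_frame([seg for seg, _ in catalog.entries])
    df.insert(0, "source", catalog.sources)
    df["cluster"] = catalog.labels if catalog.labels is not None else -1
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_catalog_csv(path) -> StateCatalog:
    df = pd.read_csv(path, float_precision="round_trip")
    entries = [
        (
            StateSegment(
                start_frame=int(r.start_frame),
                end_frame=int(r.end_frame),
                mean_twist=float(r.mean_deg),
                sigma=float(r.sigma_deg),
                lifetime_ns=float(r.lifetime_ns),
            ),
            str(r.source),
        )
        for r in df.itertuples()
    ]
    labels = None
    if "cluster" in df.columns and (df["cluster"] >= 0).all():
        labels = df["cluster"].to_numpy(dtype=int)
    return StateCatalog(entries=entries, labels=labels)


def write_moduli_csv(catalog: StateCatalog, moduli, path) -> None:
    df = pd.DataFrame(
        {
            "source": catalog.sources,
            "mean_deg": catalog.means,
            "sigma_deg": catalog.sigmas,
            "lifetime_ns": catalog.lifetimes_ns,
            "K_kT_nm": [m.K_kT_nm for m in moduli],
            "K_pN_nm2": [m.K_pN_nm2 for m in moduli],
            "temperature_K": [m.temperature for m in moduli],
            "monomer_length_nm": [m.monomer_length for m in moduli],
        }
    )
    if catalog.labels is not None:
        df["cluster"] = catalog.labels
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


# ---------------------------------------------------------------------------
# Structures (PDB)


def fetch_pdb(pdb_id: str, dest) -> Path:
    """Download a PDB entry from RCSB (requires network; not used by tests)."""
    dest = Path(dest)
    url = f"https://files.rcsb.org/download/{pdb_id.upper()}.pdb"
    with urllib.request.urlopen(url, timeout=60) as resp:
        dest.write_bytes(resp.read())
    return dest


def _radius_for_element(element: str) -> float:
    key = element.strip().upper()
    if key not in VDW_RADII:
        raise KeyError(
            f"no van der Waals radius for element {element!r}; "
            f"known elements: {sorted(VDW_RADII)}"
        )
    return VDW_RADII[key]


def _gemmi():
    import gemmi

    return gemmi


def read_structure(path):
    """Read a PDB file into ToyStructure(s) with per-element radii.

    Single-MODEL files return one :class:`ToyStructure` (group labels are
    chain names); multi-MODEL files return a list, one per model.  altLoc
    duplicates keep the highest-occupancy conformer (logged).
    """
    gemmi = _gemmi()
    path = Path(path)
    try:
        st = gemmi.read_pdb(str(path))
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"{path}: malformed PDB ({exc})") from exc
    if len(st) == 0:
        raise ValueError(f"{path}: no models found")

    models = []
    for model in st:
        positions, radii, groups, names = [], [], [], []
        for chain in model:
            for residue in chain:
                by_name: dict[str, object] = {}
                dropped = 0
                for atom in residue:
                    prev = by_name.get(atom.name)
                    if prev is None or atom.occ > prev.occ:
                        if prev is not None:
                            dropped += 1
                        by_name[atom.name] = atom
                    else:
                        dropped += 1
                if dropped:
                    logger.info(
                        "%s: kept highest-occupancy altLoc for %s %s (%d dropped)",
                        path.name,
                        chain.name,
                        residue.seqid.num,
                        dropped,
                    )
                for atom in by_name.values():
                    positions.append([atom.pos.x, atom.pos.y, atom.pos.z])
                    radii.append(_radius_for_element(atom.element.name))
                    groups.append(chain.name)
                    names.append(f"{chain.name}/{residue.seqid.num}/{atom.name}")
        if not positions:
            raise ValueError(f"{path}: model contains no atoms")
        models.append(
            ToyStructure(
                positions=np.array(positions),
                radii=np.array(radii),
                groups=np.array(groups, dtype=object),
                names=names,
                metadata={"path": str(path), "unit": "angstrom"},
            )
        )
    return models[0] if len(models) == 1 else models


def filament_trajectory_from_pdb(
    path, pair_layout: list[tuple[str, str]], subdomains=MREB_SUBDOMAINS
) -> FilamentTrajectory:
    """Build a filament trajectory from a (multi-)MODEL PDB of subunit chains.

    ``pair_layout`` orders the antiparallel pairs along the filament axis as
    (protofilament-1 chain, protofilament-2 chain) tuples.  Each subunit is
    reduced to five reference points: the C-alpha centroid plus the C-alpha
    centroids of the four fold subdomains (robust to side-chain noise; falls
    back to all-atom centroids replicated when no C-alpha/subdomain residues
    are present, e.g. for coarse toy fixtures).
    """
    gemmi = _gemmi()
    st = gemmi.read_pdb(str(path))
    if len(st) == 0:
        raise ValueError(f"{path}: no models found")

    def subunit_points(model, chain_name: str) -> np.ndarray:
        chain = model.find_chain(chain_name)
        if chain is None:
            raise ValueError(f"{path}: chain {chain_name!r} not found")
        ca = {}
        allpos = []
        for residue in chain:
            for atom in residue:
                p = [atom.pos.x, atom.pos.y, atom.pos.z]
                allpos.append(p)
                if atom.name == "CA":
                    ca[residue.seqid.num] = p
        if not allpos:
            raise ValueError(f"{path}: chain {chain_name!r} is empty")
        if not ca:
            c = np.mean(allpos, axis=0)
            return np.tile(c, (5, 1))
        ca_pos = np.array(list(ca.values()))
        points = [ca_pos.mean(axis=0)]
        for ranges in subdomains.values():
            sel = [
                p
                for num, p in ca.items()
                if any(lo <= num <= hi for lo, hi in ranges)
            ]
            points.append(np.mean(sel, axis=0) if sel else ca_pos.mean(axis=0))
        return np.array(points)

    frames = []
    for model in st:
        pairs = []
        for chain_a, chain_b in pair_layout:
            pairs.append(
                [subunit_points(model, chain_a), subunit_points(model, chain_b)]
            )
        frames.append(pairs)
    coords = np.array(frames)
    return FilamentTrajectory(
        coords=coords,
        times=np.arange(coords.shape[0], dtype=float),
        unit="angstrom",
        metadata={"source": str(path), "pair_layout": pair_layout},
    )


def write_filament_pdb(traj: FilamentTrajectory, path) -> None:
    """Write a synthetic trajectory as multi-MODEL PDB (pseudo-atoms).

    Chains A/B are the two protofilaments, residue number is the pair index
    (1-based), the five reference points per subunit are carbon pseudo-atoms
    M1..M5.  nm coordinates are converted to angstrom.
    """
    scale = 10.0 if traj.unit == "nm" else 1.0
    lines = []
    for t in range(traj.n_frames):
        lines.append(f"MODEL     {t + 1:4d}")
        serial = 1
        for i in range(traj.n_pairs):
            for s, chain in enumerate("AB"):
                for p in range(traj.coords.shape[3]):
                    x, y, z = traj.coords[t, i, s, p] * scale
                    lines.append(
                        f"ATOM  {serial:5d}  M{p + 1:<2d}SUB {chain}{i + 1:4d}    "
                        f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          "
                        f" C  "
                    )
                    serial += 1
        lines.append("ENDMDL")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def read_filament_pdb(path) -> FilamentTrajectory:
    """Read a multi-MODEL pseudo-atom PDB written by :func:`write_filament_pdb`.

    Returns coordinates in nm (the writer's inverse).
    """
    gemmi = _gemmi()
    st = gemmi.read_pdb(str(path))
    frames = []
    for model in st:
        by_key: dict[tuple[int, int], list] = {}
        for chain in model:
            s = {"A": 0, "B": 1}.get(chain.name)
            if s is None:
                raise ValueError(f"{path}: unexpected chain {chain.name!r}")
            for residue in chain:
                pts = [[a.pos.x, a.pos.y, a.pos.z] for a in residue]
                by_key[(residue.seqid.num - 1, s)] = pts
        n_pairs = 1 + max(k[0] for k in by_key)
        frame = [
            [by_key[(i, 0)], by_key[(i, 1)]] for i in range(n_pairs)
        ]
        frames.append(frame)
    coords = np.array(frames) / 10.0
    return FilamentTrajectory(
        coords=coords,
        times=np.arange(coords.shape[0], dtype=float),
        unit="nm",
        metadata={"source": str(path)},
    )


def write_filament_table(traj: FilamentTrajectory, csv_path, json_path) -> None:
    """Binary-free coordinate table: long CSV plus a JSON metadata sidecar."""
    t, i, s, p = np.meshgrid(
        np.arange(traj.n_frames),
        np.arange(traj.n_pairs),
        np.arange(2),
        np.arange(traj.coords.shape[3]),
        indexing="ij",
    )
    flat = traj.coords.reshape(-1, 3)
    pd.DataFrame(
        {
            "frame": t.ravel(),
            "pair": i.ravel(),
            "subunit": s.ravel(),
            "point": p.ravel(),
            "x": flat[:, 0],
            "y": flat[:, 1],
            "z": flat[:, 2],
        }
    ).to_csv(csv_path, index=False, float_format=_FLOAT_FMT)
    meta = {
        "unit": traj.unit,
        "times_ns": traj.times.tolist(),
        "shape": list(traj.coords.shape),
        "metadata": _jsonable(traj.metadata),
    }
    Path(json_path).write_text(json.dumps(meta, indent=1, sort_keys=True))


def read_filament_table(csv_path, json_path) -> FilamentTrajectory:
    meta = json.loads(Path(json_path).read_text())
    df = pd.read_csv(csv_path, float_precision="round_trip")
    shape = tuple(meta["shape"])
    order = np.lexsort((df["point"], df["subunit"], df["pair"], df["frame"]))
    coords = df[["x", "y", "z"]].to_numpy()[order].reshape(shape)
    return FilamentTrajectory(
        coords=coords,
        times=np.array(meta["times_ns"], dtype=float),
        unit=meta["unit"],
        metadata=meta.get("metadata", {}),
    )


# ---------------------------------------------------------------------------
# Pipeline


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


@dataclass
class PipelineConfig:
    """Declarative configuration of one end-to-end run.

    ``inputs`` is a list of stage-1 sources, each a mapping with a ``kind``:
    ``{"kind": "preset", "name": "atp1", "seed": 7}``,
    ``{"kind": "trace_csv", "path": "...", "label": "..."}`` or
    ``{"kind": "pdb", "path": "...", "pair_layout": [["A","E"], ...]}``.
    """

    inputs: list[dict]
    out_dir: str
    seed: int = 0
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    n_clusters: int | str = 4  # or "auto" for silhouette selection
    temperature: float = 310.0
    monomer_length: float = 5.0
    bin_width: float = 0.5
    weighted_histogram: bool = False

    def __post_init__(self) -> None:
        if not self.inputs:
            raise ValueError("config lists no inputs")
        if isinstance(self.segmentation, dict):
            self.segmentation = SegmentationParams(**self.segmentation)
        for spec in self.inputs:
            if spec.get("kind") not in ("preset", "trace_csv", "pdb"):
                raise ValueError(f"unknown input kind in {spec!r}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise ValueError(f"{path}: config must be a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**raw)

    def snapshot(self) -> dict:
        d = dataclasses.asdict(self)
        return _jsonable(d)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.snapshot(), sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class RunManifest:
    """Provenance record emitted by every pipeline run."""

    version: str
    config: dict
    config_hash: str
    file_hashes: dict[str, str]
    started_at: str
    finished_at: str

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _load_input_trace(spec: dict, base_seed: int) -> tuple[str, TwistTrace]:
    kind = spec["kind"]
    if kind == "preset":
        seed = spec.get("seed", base_seed)
        kwargs = {
            k: v for k, v in spec.items() if k not in ("kind", "name", "seed", "label")
        }
        schedule = preset_schedule(spec["name"], seed=seed, **kwargs)
        label = spec.get("label", f"{spec['name']}-seed{seed}")
        return label, gen_twist_trace(schedule)
    if kind == "trace_csv":
        label = spec.get("label", Path(spec["path"]).stem)
        return label, read_trace_csv(spec["path"])
    # kind == "pdb": extract the twist trace from coordinates
    traj = filament_trajectory_from_pdb(spec["path"], spec["pair_layout"])
    label = spec.get("label", Path(spec["path"]).stem)
    trace = middle_doublet_twist(traj)
    return label, trace


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute twist extraction/ingestion -> segmentation -> clustering -> moduli.

    Writes per-source segment CSVs, the pooled catalog CSV, the moduli CSV
    and a JSON summary into ``config.out_dir``, plus a manifest; aborts with
    the failing stage named.  Idempotent for a fixed seed and inputs (all
    numeric outputs byte-identical; timestamps live only in the manifest).
    """
    started = time.strftime("%Y-%m-%dT%H:%M:%S")
    # Validate all referenced paths before any stage runs.
    for spec in config.inputs:
        if "path" in spec and not Path(spec["path"]).exists():
            raise FileNotFoundError(f"input not found: {spec['path']}")
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    outputs: list[Path] = []

    def stage(name):
        logger.info("pipeline stage: %s", name)

    try:
        stage("ingest")
        traces = [_load_input_trace(spec, config.seed) for spec in config.inputs]
    except Exception as exc:
        raise RuntimeError(f"pipeline failed in stage 'ingest': {exc}") from exc

    try:
        stage("segment")
        segments_by_source: dict[str, list[StateSegment]] = {}
        for label, trace in traces:
            segs = detect_states(trace, config.segmentation)
            segments_by_source[label] = segs
            p = out_dir / f"segments_{label}.csv"
            write_segments_csv(segs, p)
            outputs.append(p)
    except Exception as exc:
        raise RuntimeError(f"pipeline failed in stage 'segment': {exc}") from exc

    try:
        stage("cluster")
        catalog = StateCatalog.from_segments(segments_by_source)
        if config.n_clusters == "auto":
            k = select_n_clusters(catalog, seed=config.seed)
        else:
            k = int(config.n_clusters)
        catalog = cluster_state_means(catalog, n_clusters=k, seed=config.seed)
        p = out_dir / "catalog.csv"
        write_catalog_csv(catalog, p)
        outputs.append(p)
    except Exception as exc:
        raise RuntimeError(f"pipeline failed in stage 'cluster': {exc}") from exc

    try:
        stage("modulus")
        moduli = moduli_for_catalog(
            catalog, temperature=config.temperature, monomer_length=config.monomer_length
        )
        p = out_dir / "moduli.csv"
        write_moduli_csv(catalog, moduli, p)
        outputs.append(p)
    except Exception as exc:
        raise RuntimeError(f"pipeline failed in stage 'modulus': {exc}") from exc

    summary = {
        "config_hash": chash,
        "seed": config.seed,
        "n_sources": len(traces),
        "n_states": len(catalog),
        "n_clusters": int(k),
        "centroids_deg": catalog.centroids.tolist(),
        "median_K_kT_nm": float(np.median([m.K_kT_nm for m in moduli])),
        "temperature_K": config.temperature,
    }
    p = out_dir / "summary.json"
    p.write_text(json.dumps(summary, indent=1, sort_keys=True))
    outputs.append(p)

    manifest = RunManifest(
        version=__version__,
        config=config.snapshot(),
        config_hash=chash,
        file_hashes={str(f.name): _sha256(f) for f in outputs},
        started_at=started,
        finished_at=time.strftime("%Y-%m-%dT%H:%M:%S"),
    )
    manifest.write(out_dir / "manifest.json")
    return manifest


def convention_report(traj: FilamentTrajectory) -> dict:
    """Frame-convention sensitivity of the measured twist (user-facing).

    The triad convention (which points define the pair centroids and the d2
    seed) is not uniquely determined for real structures; absolute twist
    values should be quoted together with this report.
    """
    return frame_convention_sensitivity(traj)
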