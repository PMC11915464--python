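"""End-to-end cap design pipeline and its JSON-serializable configuration.

Stages: (optional) surface extraction -> landmark computation -> cap build
(coarsen, register, grommets, holes, margins, wireframe) -> printable
re-tessellation and repair -> metrology validation.  Identical configs and
inputs produce byte-identical landmark JSON and defect reports.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh

from . import capbuild, metrology, printable
from .capbuild import CapParams, GrommetSpec
from .errors import ValidationError
from .landmarks import Fiducials, LandmarkSet, compute_landmarks
from .mesh_io import read_mesh, read_volume, write_mesh
from .surface_extract import ExtractionParams, extract_head_surface

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "CapBuildResult", "build_cap", "validate_cap",
           "run_pipeline"]


@dataclass
class RunConfig:
    """Every pipeline parameter with its default, JSON round-trippable."""

    input_mesh: str | None = None
    input_volume: str | None = None
    fiducials: str | None = None
    output_dir: str = "capforge_out"
    system: str = "10-10"
    threshold: float | None = None
    max_circumradius: float = 2.0
    smoothing_iterations: int = 5
    grommet_shape: str = "circle"
    grommet_radius: float = 4.0
    grommet_depth: float = 20.0
    keep_ratio: float = 0.05
    wire_thickness: float = 2.5
    face_width_fraction: float = 1.0 / 3.0
    face_height_fraction: float = 0.25
    neck_height_fraction: float = 1.0 / 3.0
    ear_cutout: bool = False
    margin_band_width: float = 10.0
    voxel_pitch: float | None = None  # default: wire_thickness / 4
    seed: int = 0
    verbosity: str = "INFO"

    def __post_init__(self):
        # delegate numeric validation to the parameter dataclasses
        self.cap_params()
        self.grommet_spec()

    def cap_params(self) -> CapParams:
        return CapParams(
            keep_ratio=self.keep_ratio,
            wire_thickness=self.wire_thickness,
            face_width_fraction=self.face_width_fraction,
            face_height_fraction=self.face_height_fraction,
            neck_height_fraction=self.neck_height_fraction,
            ear_cutout=self.ear_cutout,
            margin_band_width=self.margin_band_width,
        )

    def grommet_spec(self) -> GrommetSpec:
        return GrommetSpec(shape=self.grommet_shape,
                           radius=self.grommet_radius,
                           cutter_depth=self.grommet_depth)

    def extraction_params(self) -> ExtractionParams:
        return ExtractionParams(threshold=self.threshold,
                                max_circumradius=self.max_circumradius,
                                smoothing_iterations=self.smoothing_iterations)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        data = json.loads(text)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


@dataclass
class CapBuildResult:
    """All intermediate artifacts of a cap build."""

    landmarks: LandmarkSet           # on the original fine surface
    coarse: trimesh.Trimesh          # decimated cap body
    registered: LandmarkSet          # landmarks snapped onto the coarse body
    holed: trimesh.Trimesh           # after grommet subtraction
    cap: trimesh.Trimesh             # after margin cuts + margin tags
    surviving: list[str] = field(default_factory=list)
    wireframe_solid: trimesh.Trimesh | None = None
    printable_mesh: trimesh.Trimesh | None = None
    defect_report: printable.MeshDefectReport | None = None


def build_cap(mesh: trimesh.Trimesh, landmarks: LandmarkSet,
              cap_params: CapParams | None = None,
              grommet: GrommetSpec | None = None,
              voxel_pitch: float | None = None,
              solidify: bool = True,
              check_self_intersections: bool = True) -> CapBuildResult:
    """Run the cap construction chain on a head surface with landmarks."""
    if cap_params is None:
        cap_params = CapParams()
    if grommet is None:
        grommet = GrommetSpec()
    if grommet.cutter_depth < 4 * cap_params.wire_thickness:
        raise ValidationError(
            "grommet cutter depth must span the wireframed surface "
            f"(>= 4x wire thickness = {4 * cap_params.wire_thickness} mm)")
    fiducials = landmarks.fiducials
    if fiducials is None:
        raise ValidationError("landmark set must carry its fiducials")

    coarse = capbuild.coarsen(mesh, cap_params.keep_ratio)
    registered = capbuild.register_landmarks(landmarks, coarse)
    cutters = capbuild.place_grommets(coarse, registered, grommet)
    holed = capbuild.cut_grommet_holes(coarse, cutters)
    capped = capbuild.cut_margins(holed, fiducials, cap_params)
    capped = capbuild.thicken_margin(capped, cap_params.margin_band_width)

    boxes = capbuild.margin_boxes(holed, fiducials, cap_params)
    surviving = [lbl for lbl in registered.labels()
                 if not capbuild.point_in_any_box(registered[lbl], boxes)]

    result = CapBuildResult(landmarks=landmarks, coarse=coarse,
                            registered=registered, holed=holed, cap=capped,
                            surviving=surviving)
    if not solidify:
        return result
    solid = capbuild.wireframe(capped, cap_params.wire_thickness,
                               strict_edge_check=False)
    pitch = voxel_pitch if voxel_pitch is not None else cap_params.wire_thickness / 4.0
    fused = printable.remesh_solidify(solid, pitch)
    final = printable.repair(
        fused, check_self_intersections=check_self_intersections)
    result.wireframe_solid = solid
    result.printable_mesh = final
    result.defect_report = final.metadata["defect_report"]
    return result


def validate_cap(mesh: trimesh.Trimesh, result: CapBuildResult,
                 grommet_radius: float,
                 reference: dict[str, dict[str, float]] | None = None
                 ) -> metrology.ValidationReport:
    """Computational analog of the printed-head landmark validation.

    Grommet-hole centroids recovered from the built cap are radially
    projected onto the head surface (center = preauricular midpoint) and
    measured along the sagittal and coronal reference curves; the reference
    distances default to those of the computed landmarks themselves.
    """
    landmarks = result.landmarks
    fid = landmarks.fiducials
    centroids = metrology.grommet_hole_centroids(result.cap, result.registered,
                                                 grommet_radius)
    frame_origin = metrology.CanonicalFrame.from_fiducials(fid).origin
    if reference is None:
        reference = {
            row: metrology.geodesic_landmark_distances(mesh, landmarks, row)
            for row in ("sagittal", "coronal")
        }
    ref_all: dict[str, float] = {}
    mes_all: dict[str, float] = {}
    for row in ("sagittal", "coronal"):
        row_labels = [l for l in metrology.ROW_LABELS[row] if l in centroids]
        if row == "coronal":
            row_labels = [l for l in row_labels if l != "Cz"]
        if not row_labels:
            continue
        pts = np.stack([centroids[l] for l in row_labels])
        projected = metrology.radial_project(pts, frame_origin, mesh)
        measured = metrology.measure_along_row(
            mesh, landmarks, row,
            dict(zip(row_labels, np.atleast_2d(projected))))
        for l in row_labels:
            if l in reference[row]:
                key = l if l not in ref_all else f"{l}({row})"
                ref_all[key] = reference[row][l]
                mes_all[key] = measured[l]
    return metrology.landmark_error_stats(ref_all, mes_all)


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Execute the full pipeline per ``config``; returns artifact paths."""
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}

    def fail(stage, exc):
        raise type(exc)(
            f"pipeline stage {stage!r} failed ({exc}); completed artifacts: "
            f"{ {k: str(v) for k, v in artifacts.items()} }") from exc

    # ------------------------------------------------------------------ input
    if config.input_volume:
        try:
            vol = read_volume(config.input_volume)
            mesh = extract_head_surface(vol, config.extraction_params())
        except Exception as exc:  # noqa: BLE001
            fail("extract-surface", exc)
        head_path = out_dir / "head.stl"
        write_mesh(mesh, head_path)
        artifacts["head_mesh"] = head_path
    elif config.input_mesh:
        mesh = read_mesh(config.input_mesh)
    else:
        raise ValidationError("config needs input_mesh or input_volume")
    if not config.fiducials:
        raise ValidationError("config needs a fiducials JSON path")
    fid = Fiducials.from_dict(json.loads(Path(config.fiducials).read_text()))

    # -------------------------------------------------------------- landmarks
    try:
        landmarks = compute_landmarks(mesh, fid, config.system)
    except Exception as exc:  # noqa: BLE001
        fail("landmarks", exc)
    lm_path = out_dir / "landmarks.json"
    lm_path.write_text(json.dumps(landmarks.as_dict(), indent=2,
                                  sort_keys=True))
    artifacts["landmarks"] = lm_path

    # -------------------------------------------------------------- build-cap
    try:
        result = build_cap(mesh, landmarks, config.cap_params(),
                           config.grommet_spec(),
                           voxel_pitch=config.voxel_pitch)
    except Exception as exc:  # noqa: BLE001
        fail("build-cap", exc)
    cap_path = out_dir / "cap.stl"
    write_mesh(result.printable_mesh, cap_path)
    artifacts["cap"] = cap_path
    report_path = out_dir / "defect_report.json"
    report_path.write_text(json.dumps(result.defect_report.as_dict(),
                                      indent=2, sort_keys=True))
    artifacts["defect_report"] = report_path

    # ---------------------------------------------------------------- measure
    try:
        validation = validate_cap(mesh, result, config.grommet_radius)
        circ = metrology.circumference(mesh, landmarks)
    except Exception as exc:  # noqa: BLE001
        fail("measure", exc)
    val_path = out_dir / "validation.json"
    payload = validation.as_dict()
    payload["circumference_mm"] = float(circ)
    payload["surviving_landmarks"] = sorted(result.surviving)
    val_path.write_text(json.dumps(payload, indent=2, sort_keys=True))
    artifacts["validation"] = val_path

    config_path = out_dir / "config_echo.json"
    config_path.write_text(config.to_json())
    artifacts["config"] = config_path
    log.info("pipeline complete: %s", {k: str(v) for k, v in artifacts.items()})
    return artifacts
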