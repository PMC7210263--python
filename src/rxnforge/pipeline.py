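"""Orchestration of the reaction-generation campaign.

Stages, in order: reactant preparation (conformer embedding, force-field
relaxation, opt+freq job), driving-coordinate enumeration, string-path
search (executor), product optimization (executor), duplicate retention
(up to four lowest-barrier candidates per reaction), transition-state
optimization (executor), perception and atom-map reconstruction,
verification, energetics, final deduplication (lowest barrier wins), and
dataset assembly in the published layout (CSV with columns
``idx,rsmi,psmi,ea,dh`` next to per-reaction ``rxn######`` directories
holding ``r/p/ts######.log``).

The external engine is a contract, not a dependency: anything with a
``run(job_text) -> output_text`` method works.  Failed jobs are data (a
status in the campaign state), never exceptions that abort a campaign.
Campaign state lives on disk (``state.json`` plus job/log files), so a
killed campaign resumes from the last completed stage, and with the
deterministic mock engine the final CSV is bit-reproducible for a given
(inputs, config, seed).
"""

from __future__ import annotations

import json
import shutil
import tarfile
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem, rdDistGeom

from rxnforge import perception, qcio
from rxnforge.driving import (
    DrivingCoordinateSet,
    EnumerationConstraints,
    enumerate_driving_coordinates,
)
from rxnforge.energetics import SpeciesEnergetics, activation_energy, reaction_enthalpy
from rxnforge.mocks import GSM_FAILURE_MARKER, make_gsm_job, make_tsopt_comment
from rxnforge.molgraph import MolGraph, bond_changes
from rxnforge.verify import NoReactionError, VerificationReport, verify_reaction

STAGES = (
    "prepare",
    "enumerate",
    "gsm",
    "prodopt",
    "retain",
    "tsopt",
    "extract",
    "finalize",
)

CSV_HEADER = "idx,rsmi,psmi,ea,dh"


class PipelineError(RuntimeError):
    """Campaign-level failure (bad config, broken workspace)."""


class PreparationError(PipelineError):
    """A reactant could not be embedded/prepared."""


class PackagingError(PipelineError):
    """Dataset packaging failed (missing provenance files)."""


@dataclass
class PipelineConfig:
    """Campaign settings: level of theory, search constraints, thresholds, seed."""

    method: str = "B97-D3"
    basis: str = "def2-mSVP"
    n_conformers: int = 300
    constraints: EnumerationConstraints = field(default_factory=EnumerationConstraints)
    perception_tol: float = 1.2
    imag_min_magnitude: float = 100.0  # cm^-1
    drift_tol: float = 3.0  # kcal/mol
    max_duplicates_retained: int = 4
    string_nodes: int = 9
    seed: int = 0

    @property
    def level_tag(self) -> str:
        return f"{self.method}/{self.basis}"

    def engine_config(self, job_type: str) -> qcio.EngineConfig:
        return qcio.EngineConfig(self.method, self.basis, job_type)


@dataclass(frozen=True)
class ReactionKey:
    """Order-independent identity of a reaction: reactant key + product fragment keys."""

    reactant: str
    products: Tuple[str, ...]

    @staticmethod
    def make(reactant_key: str, product_keys: Iterable[str]) -> "ReactionKey":
        return ReactionKey(reactant_key, tuple(sorted(product_keys)))

    def as_str(self) -> str:
        return self.reactant + ">>" + "|".join(self.products)


@dataclass
class ReactionRecord:
    """One curated reaction with its energetics, provenance and verification report."""

    idx: int
    rsmi: str
    psmi: str
    ea: float  # kcal/mol
    dh: float  # kcal/mol
    level_tag: str
    key: ReactionKey
    provenance: Dict[str, str] = field(default_factory=dict)
    report: Optional[VerificationReport] = None

    def __post_init__(self) -> None:
        if not (np.isfinite(self.ea) and np.isfinite(self.dh)):
            raise PipelineError("non-finite energetics in a reaction record")


# ---------------------------------------------------------------------------
# reactant preparation
# ---------------------------------------------------------------------------


def prepare_reactant(
    smiles: str, n_conformers: int, seed: int
) -> Tuple[MolGraph, np.ndarray]:
    """Embed conformers, relax with MMFF94, return graph + lowest-energy geometry.

    The graph carries the original (SMILES-derived, explicit-hydrogen)
    atom indices; the geometry rows follow the same order.  Deterministic
    for a given seed.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise PreparationError(f"unparsable SMILES: {smiles!r}")
    for atom in mol.GetAtoms():
        if atom.GetSymbol() not in ("H", "C", "N", "O"):
            raise PreparationError(f"unsupported element {atom.GetSymbol()} in {smiles!r}")
    mol = Chem.AddHs(mol)
    params = rdDistGeom.ETKDGv3()
    params.randomSeed = int(seed) % (2**31 - 1)
    conf_ids = rdDistGeom.EmbedMultipleConfs(mol, numConfs=max(1, n_conformers), params=params)
    if not conf_ids:
        raise PreparationError(f"conformer embedding failed for {smiles!r}")
    results = AllChem.MMFFOptimizeMoleculeConfs(mol, maxIters=500)
    energies = [
        (e if ok == 0 else float("inf"), cid)
        for (ok, e), cid in zip(results, conf_ids)
    ]
    finite = [t for t in energies if np.isfinite(t[0])]
    best = min(finite or energies, key=lambda t: (t[0], t[1]))[1]
    geometry = mol.GetConformer(int(best)).GetPositions()
    graph = perception.graph_from_rdkit(mol)
    return graph.with_coordinates(geometry), geometry


# ---------------------------------------------------------------------------
# duplicate handling
# ---------------------------------------------------------------------------


def retain_candidates(candidates: Sequence[dict], k: int = 4) -> List[dict]:
    """Per reaction key, keep the k lowest provisional-barrier candidates.

    Each candidate dict needs ``key`` (a string or ReactionKey) and
    ``barrier``; ties are broken by discovery order (input position).
    Output preserves input order.
    """
    groups: Dict[object, List[int]] = {}
    for pos, cand in enumerate(candidates):
        groups.setdefault(cand["key"], []).append(pos)
    keep: set = set()
    for positions in groups.values():
        ranked = sorted(positions, key=lambda p: (candidates[p]["barrier"], p))
        keep.update(ranked[:k])
    return [c for p, c in enumerate(candidates) if p in keep]


def dedup_final(records: Sequence[ReactionRecord]) -> List[ReactionRecord]:
    """One record per ReactionKey: the minimum-ea one; stable order by idx."""
    best: Dict[ReactionKey, ReactionRecord] = {}
    for rec in records:
        cur = best.get(rec.key)
        if cur is None or (rec.ea, rec.idx) < (cur.ea, cur.idx):
            best[rec.key] = rec
    return sorted(best.values(), key=lambda r: r.idx)


# ---------------------------------------------------------------------------
# dataset layout
# ---------------------------------------------------------------------------


def format_csv(records: Sequence[ReactionRecord]) -> str:
    lines = [CSV_HEADER]
    for rec in records:
        lines.append(f"{rec.idx},{rec.rsmi},{rec.psmi},{rec.ea:.6f},{rec.dh:.6f}")
    return "\n".join(lines) + "\n"


def write_dataset(
    records: Sequence[ReactionRecord], out_dir: Path, csv_name: str = "reactions.csv"
) -> Path:
    """Write the CSV and the per-reaction rxn%06d directories.

    Each directory holds r/p/ts%06d.log copied from the record's
    provenance; CSV row order equals directory order.  Returns the CSV
    path.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    csv_path = out_dir / csv_name
    csv_path.write_text(format_csv(records))
    for rec in records:
        rxn_dir = out_dir / f"rxn{rec.idx:06d}"
        rxn_dir.mkdir(exist_ok=True)
        for kind in ("r", "p", "ts"):
            src = rec.provenance.get(kind)
            if not src or not Path(src).exists():
                raise PackagingError(f"reaction {rec.idx}: missing {kind} log ({src})")
            shutil.copyfile(src, rxn_dir / f"{kind}{rec.idx:06d}.log")
    return csv_path


def package_tarball(out_dir: Path, tar_path: Path) -> Path:
    """Optional tar.gz of an assembled dataset directory."""
    tar_path = Path(tar_path)
    with tarfile.open(tar_path, "w:gz") as tar:
        tar.add(out_dir, arcname=Path(out_dir).name)
    return tar_path


def write_ts_collection(ts_log_paths: Sequence[str], out_dir: Path) -> List[Path]:
    """TS-only collection (all successfully optimized TSs, duplicates included)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for k, src in enumerate(ts_log_paths):
        if not Path(src).exists():
            raise PackagingError(f"missing TS log {src}")
        dst = out_dir / f"ts{k:06d}.log"
        shutil.copyfile(src, dst)
        written.append(dst)
    return written


# ---------------------------------------------------------------------------
# the campaign
# ---------------------------------------------------------------------------


class Campaign:
    """On-disk, stage-resumable reaction-generation campaign."""

    def __init__(self, smiles_list: Sequence[str], config: PipelineConfig, executor, workdir):
        self.smiles = list(smiles_list)
        self.config = config
        self.executor = executor
        self.workdir = Path(workdir)
        for sub in ("jobs", "logs", "string"):
            (self.workdir / sub).mkdir(parents=True, exist_ok=True)
        self.state_path = self.workdir / "state.json"
        self.state = (
            json.loads(self.state_path.read_text())
            if self.state_path.exists()
            else {"done": [], "reactants": [], "candidates": [], "records": []}
        )

    # -- persistence -----------------------------------------------------

    def _save(self) -> None:
        self.state_path.write_text(json.dumps(self.state, indent=1, sort_keys=True))

    def _mark_done(self, stage: str) -> None:
        if stage not in self.state["done"]:
            self.state["done"].append(stage)
        self._save()

    def _write(self, relpath: str, text: str) -> str:
        path = self.workdir / relpath
        path.write_text(text)
        return str(path)

    # -- stages ----------------------------------------------------------

    def run(self, stop_after: Optional[str] = None) -> Optional["Dataset"]:
        for stage in STAGES:
            if stage not in self.state["done"]:
                getattr(self, f"_stage_{stage}")()
                self._mark_done(stage)
            if stage == stop_after:
                return None
        return self.dataset()

    def dataset(self) -> "Dataset":
        records = [_record_from_json(r) for r in self.state["records"]]
        return Dataset(records, self.workdir / "dataset" / "reactions.csv", self.workdir / "dataset")

    def _stage_prepare(self) -> None:
        cfg = self.config
        for i, smiles in enumerate(self.smiles):
            rid = f"{i:04d}"
            entry = {"id": rid, "smiles": smiles, "status": "ok"}
            try:
                graph, geometry = prepare_reactant(
                    smiles, cfg.n_conformers, cfg.seed * 10007 + i
                )
            except PreparationError as exc:
                entry.update(status="failed", error=str(exc))
                self.state["reactants"].append(entry)
                continue
            job = qcio.write_engine_input(
                geometry, graph.elements, cfg.engine_config("opt+freq"), comment=f"opt {rid}"
            )
            self._write(f"jobs/opt_{rid}.in", job)
            out = self.executor.run(job)
            if out.startswith(GSM_FAILURE_MARKER):
                entry.update(status="failed", error="opt job failed")
            else:
                log_path = self._write(f"logs/r_{rid}.log", out)
                result = qcio.parse_optfreq_log(out)
                entry.update(
                    log=log_path,
                    energy=result.energy,
                    elements=list(graph.elements),
                    geometry=result.geometry.tolist(),
                    bonds=sorted(list(b) for b in graph.bonds),
                )
                if any(f < 0 for f in result.frequencies):
                    entry.update(status="failed", error="reactant has imaginary frequencies")
            self.state["reactants"].append(entry)
        self._save()

    def _reactant_graph(self, entry: dict) -> MolGraph:
        return perception.graph_from_smiles(entry["smiles"])

    def _stage_enumerate(self) -> None:
        for entry in self.state["reactants"]:
            if entry["status"] != "ok":
                continue
            graph = self._reactant_graph(entry)
            for k, dcs in enumerate(
                enumerate_driving_coordinates(graph, self.config.constraints)
            ):
                self.state["candidates"].append(
                    {
                        "id": f"{entry['id']}_{k:04d}",
                        "reactant": entry["id"],
                        "breaks": [list(b) for b in dcs.breaks],
                        "forms": [list(f) for f in dcs.forms],
                        "status": "ok",
                    }
                )
        self._save()

    def _candidates(self, status: str = "ok") -> List[dict]:
        return [c for c in self.state["candidates"] if c["status"] == status]

    def _reactant_entry(self, rid: str) -> dict:
        return next(r for r in self.state["reactants"] if r["id"] == rid)

    def _stage_gsm(self) -> None:
        for cand in self._candidates():
            entry = self._reactant_entry(cand["reactant"])
            dcs = DrivingCoordinateSet.make(cand["breaks"], cand["forms"])
            job = make_gsm_job(
                entry["elements"], np.array(entry["geometry"]), dcs, cand["id"]
            )
            self._write(f"jobs/gsm_{cand['id']}.in", job)
            out = self.executor.run(job)
            if out.startswith(GSM_FAILURE_MARKER):
                cand["status"] = "gsm_failed"
            else:
                cand["string"] = self._write(f"string/gsm{cand['id']}.out", out)
        self._save()

    def _stage_prodopt(self) -> None:
        cfg = self.config
        for cand in self._candidates():
            string = qcio.parse_string_output(Path(cand["string"]).read_text())
            job = qcio.write_engine_input(
                string.endpoint_geometry,
                string.elements,
                cfg.engine_config("opt+freq"),
                comment=f"prodopt {cand['id']}",
            )
            self._write(f"jobs/prod_{cand['id']}.in", job)
            out = self.executor.run(job)
            if out.startswith(GSM_FAILURE_MARKER):
                cand["status"] = "prodopt_failed"
                continue
            log_path = self._write(f"logs/p_{cand['id']}.log", out)
            result = qcio.parse_optfreq_log(out)
            entry = self._reactant_entry(cand["reactant"])
            rg = self._reactant_graph(entry)
            try:
                pg = perception.perceive_connectivity(
                    result.elements, result.geometry, cfg.perception_tol
                )
                broken, formed = bond_changes(rg, pg)
            except perception.PerceptionError:
                cand["status"] = "perception_failed"
                continue
            if not broken and not formed:
                cand["status"] = "no_reaction"
                continue
            p_perceived = perception.perceived_from_graph(pg)
            frag_keys = [
                frag.identity_key for frag, _ in perception.split_fragments(p_perceived)
            ]
            r_key = perception.identity_key(rg)
            cand.update(
                p_log=log_path,
                key=ReactionKey.make(r_key, frag_keys).as_str(),
                barrier=string.max_energy - string.node_energies[0],
                changing=sorted([list(b) for b in broken] + [list(f) for f in formed]),
                unchanged=sorted(
                    list(b)
                    for b in (set(rg.bonds) | set(pg.bonds))
                    - (broken | formed)
                ),
            )
        self._save()

    def _stage_retain(self) -> None:
        live = self._candidates()
        kept = retain_candidates(live, self.config.max_duplicates_retained)
        kept_ids = {c["id"] for c in kept}
        for cand in live:
            if cand["id"] not in kept_ids:
                cand["status"] = "duplicate_dropped"
        self._save()

    def _stage_tsopt(self) -> None:
        cfg = self.config
        for cand in self._candidates():
            string = qcio.parse_string_output(Path(cand["string"]).read_text())
            comment = make_tsopt_comment(
                cand["id"],
                string.max_energy,
                [tuple(b) for b in cand["changing"]],
                [tuple(b) for b in cand["unchanged"]],
            )
            job = qcio.write_engine_input(
                string.ts_geometry,
                string.elements,
                cfg.engine_config("ts-opt+freq"),
                comment=comment,
            )
            self._write(f"jobs/ts_{cand['id']}.in", job)
            out = self.executor.run(job)
            if out.startswith(GSM_FAILURE_MARKER):
                cand["status"] = "tsopt_failed"
            else:
                cand["ts_log"] = self._write(f"logs/ts_{cand['id']}.log", out)
        self._save()

    def _stage_extract(self) -> None:
        cfg = self.config
        idx = 0
        for cand in self._candidates():
            entry = self._reactant_entry(cand["reactant"])
            rec = _extract_one(cand, entry, cfg)
            if rec is None:
                continue
            if not rec.report.passed:
                cand["status"] = "verification_failed"
                cand["report"] = _report_to_json(rec.report)
                continue
            rec.idx = idx
            idx += 1
            self.state["records"].append(_record_to_json(rec))
        self._save()

    def _stage_finalize(self) -> None:
        records = dedup_final([_record_from_json(r) for r in self.state["records"]])
        for new_idx, rec in enumerate(records):  # contiguous indices after dedup
            rec.idx = new_idx
        write_dataset(records, self.workdir / "dataset")
        self.state["records"] = [_record_to_json(r) for r in records]
        self._save()


def _extract_one(cand: dict, entry: dict, cfg: PipelineConfig) -> Optional[ReactionRecord]:
    """Perceive, verify and energeticize one surviving candidate."""
    r_result = qcio.parse_optfreq_log(Path(entry["log"]).read_text())
    p_result = qcio.parse_optfreq_log(Path(cand["p_log"]).read_text())
    ts_result = qcio.parse_optfreq_log(Path(cand["ts_log"]).read_text())
    string = qcio.parse_string_output(Path(cand["string"]).read_text())
    original = perception.graph_from_smiles(entry["smiles"])
    try:
        r_perceived = perception.perceive_molecule(
            r_result.elements, r_result.geometry, cfg.perception_tol
        )
        p_perceived = perception.perceive_molecule(
            p_result.elements, p_result.geometry, cfg.perception_tol
        )
        fragments = perception.split_fragments(p_perceived)
        rsmi, psmi = perception.reaction_smiles(r_perceived, fragments, original)
    except perception.PerceptionError as exc:
        cand["status"] = "extraction_failed"
        cand["error"] = str(exc)
        return None
    try:
        report = verify_reaction(
            r_result,
            ts_result,
            p_result,
            r_perceived.graph,
            p_perceived.graph,
            string,
            imag_min_magnitude=cfg.imag_min_magnitude,
            drift_tol=cfg.drift_tol,
        )
    except NoReactionError:
        cand["status"] = "no_reaction"
        return None
    level = cfg.level_tag
    r_sp = SpeciesEnergetics.from_optfreq(r_result, level)
    ts_sp = SpeciesEnergetics.from_optfreq(ts_result, level)
    p_sp = SpeciesEnergetics.from_optfreq(p_result, level)
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ea = activation_energy(r_sp, ts_sp)
    dh = reaction_enthalpy(r_sp, [p_sp])
    key = ReactionKey.make(
        r_perceived.identity_key,
        [frag.identity_key for frag, _ in perception.split_fragments(p_perceived)],
    )
    return ReactionRecord(
        idx=-1,
        rsmi=rsmi,
        psmi=psmi,
        ea=ea,
        dh=dh,
        level_tag=level,
        key=key,
        provenance={
            "r": entry["log"],
            "p": cand["p_log"],
            "ts": cand["ts_log"],
            "string": cand["string"],
        },
        report=report,
    )


# -- record (de)serialization ------------------------------------------------


def _report_to_json(report: VerificationReport) -> dict:
    return {
        "one_imaginary": report.one_imaginary,
        "imag_magnitude_ok": report.imag_magnitude_ok,
        "energy_drift_ok": report.energy_drift_ok,
        "mode_match_ok": report.mode_match_ok,
        "endpoints_are_minima": report.endpoints_are_minima,
        "energy_drift_kcal": report.details.get("energy_drift_kcal"),
    }


def _record_to_json(rec: ReactionRecord) -> dict:
    return {
        "idx": rec.idx,
        "rsmi": rec.rsmi,
        "psmi": rec.psmi,
        "ea": rec.ea,
        "dh": rec.dh,
        "level_tag": rec.level_tag,
        "key_reactant": rec.key.reactant,
        "key_products": list(rec.key.products),
        "provenance": rec.provenance,
        "report": _report_to_json(rec.report) if rec.report else None,
    }


def _record_from_json(d: dict) -> ReactionRecord:
    report = None
    if d.get("report"):
        r = d["report"]
        report = VerificationReport(
            one_imaginary=r["one_imaginary"],
            imag_magnitude_ok=r["imag_magnitude_ok"],
            energy_drift_ok=r["energy_drift_ok"],
            mode_match_ok=r["mode_match_ok"],
            endpoints_are_minima=r["endpoints_are_minima"],
            details={"energy_drift_kcal": r.get("energy_drift_kcal")},
        )
    return ReactionRecord(
        idx=d["idx"],
        rsmi=d["rsmi"],
        psmi=d["psmi"],
        ea=d["ea"],
        dh=d["dh"],
        level_tag=d["level_tag"],
        key=ReactionKey(d["key_reactant"], tuple(d["key_products"])),
        provenance=d["provenance"],
        report=report,
    )


@dataclass
class Dataset:
    """A finished campaign: curated records plus the on-disk layout."""

    records: List[ReactionRecord]
    csv_path: Path
    out_dir: Path


def run_generation(
    smiles_list: Sequence[str],
    config: PipelineConfig,
    executor,
    workdir,
    stop_after: Optional[str] = None,
) -> Optional[Dataset]:
    """Run (or resume) the full campaign in `workdir`; returns the dataset.

    If `stop_after` names a stage, execution halts after it (simulating an
    interrupted campaign); calling again without it resumes and completes.
    """
    return Campaign(smiles_list, config, executor, workdir).run(stop_after)


def refine_pass(
    dataset: Dataset, config_b: PipelineConfig, executor, workdir
) -> Dataset:
    """Re-optimize products and TSs of an existing dataset at a second level.

    Re-emits product and TS jobs with the new level tag, re-extracts,
    re-verifies against the original string paths, and re-deduplicates
    keeping the lowest barrier per reaction key.  Warns if the two level
    tags are identical.
    """
    workdir = Path(workdir)
    (workdir / "logs").mkdir(parents=True, exist_ok=True)
    if dataset.records and dataset.records[0].level_tag == config_b.level_tag:
        import warnings

        warnings.warn("refinement level tag equals the source level tag", stacklevel=2)
    refined: List[ReactionRecord] = []
    for rec in dataset.records:
        rid = f"{rec.idx:06d}"
        r_result = qcio.parse_optfreq_log(Path(rec.provenance["r"]).read_text())
        string = qcio.parse_string_output(Path(rec.provenance["string"]).read_text())
        p_result = qcio.parse_optfreq_log(Path(rec.provenance["p"]).read_text())

        r_job = qcio.write_engine_input(
            r_result.geometry, r_result.elements, config_b.engine_config("opt+freq"),
            comment=f"opt refine-{rid}",
        )
        r_out = executor.run(r_job)
        p_job = qcio.write_engine_input(
            p_result.geometry, p_result.elements, config_b.engine_config("opt+freq"),
            comment=f"prodopt refine-{rid}",
        )
        p_out = executor.run(p_job)
        rg = perception.perceive_connectivity(r_result.elements, r_result.geometry)
        pg = perception.perceive_connectivity(p_result.elements, p_result.geometry)
        broken, formed = bond_changes(rg, pg)
        changing = sorted(broken | formed)
        unchanged = sorted((set(rg.bonds) | set(pg.bonds)) - (broken | formed))
        ts_result_old = qcio.parse_optfreq_log(Path(rec.provenance["ts"]).read_text())
        ts_job = qcio.write_engine_input(
            ts_result_old.geometry,
            ts_result_old.elements,
            config_b.engine_config("ts-opt+freq"),
            comment=make_tsopt_comment(f"refine-{rid}", string.max_energy, changing, unchanged),
        )
        ts_out = executor.run(ts_job)
        if any(out.startswith(GSM_FAILURE_MARKER) for out in (r_out, p_out, ts_out)):
            continue
        paths = {}
        for kind, out in (("r", r_out), ("p", p_out), ("ts", ts_out)):
            path = workdir / "logs" / f"{kind}_refine_{rid}.log"
            path.write_text(out)
            paths[kind] = str(path)
        paths["string"] = rec.provenance["string"]
        entry = {"smiles": rec.rsmi, "log": paths["r"]}
        cand = {
            "p_log": paths["p"],
            "ts_log": paths["ts"],
            "string": rec.provenance["string"],
            "status": "ok",
        }
        new = _extract_one(cand, entry, config_b)
        if new is None or not new.report.passed:
            continue
        new.idx = rec.idx
        new.provenance = paths
        refined.append(new)
    final = dedup_final(refined)
    for new_idx, rec in enumerate(final):
        rec.idx = new_idx
    csv_path = write_dataset(final, workdir / "dataset")
    return Dataset(final, csv_path, workdir / "dataset")
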