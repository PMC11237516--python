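"""Real-time run orchestration.

Watches a run directory laid out the way nanopore run software deposits
demultiplexed reads (``<run>/fastq_pass/<barcodeNN>/*.fastq.gz``, a flat
layout is supported too), and drives segregation → classification →
saturation per barcode as each batch file is completed. Completion is
detected by size stability across two polls; a persisted ledger of file
digests makes processing idempotent across watcher restarts. Streaming a run
file-by-file yields exactly the same final profiles and saturation statuses
as processing every file in one offline pass.
"""

from __future__ import annotations

import hashlib
import json
import time
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Optional, Sequence

from .classify import ClassifierModel, classify_read, profile_sample, read_seed
from .io import (
    AbundanceProfile,
    Kingdom,
    ReadBatch,
    SampleSheet,
    read_fastq_batches,
)
from .saturation import (
    AccumulationState,
    SaturationParams,
    SaturationStatus,
    StopDecision,
    is_saturated,
    stop_recommendation,
    update_accumulation,
)
from .segregate import (
    FilterParams,
    PrimerSet,
    ProcessedRead,
    assign_kingdom,
    default_primer_sets,
    trim_and_filter,
)


@dataclass
class MonitorConfig:
    """Everything the per-batch pipeline needs, bundled."""

    sheet: SampleSheet
    models: dict[Kingdom, ClassifierModel]
    primer_sets: Sequence[PrimerSet] = field(default_factory=default_primer_sets)
    filter_params: FilterParams = FilterParams()
    sat_params: SaturationParams = SaturationParams()
    seed: int = 0
    batch_size: int = 4000
    layout: str = "dir"


@dataclass(frozen=True)
class KingdomSnap:
    reads: int
    s_obs_history: tuple[int, ...]
    chao1_history: tuple[float, ...]
    reads_history: tuple[int, ...]
    status: SaturationStatus


@dataclass
class RunSnapshot:
    """State of the run after one processed batch (or a heartbeat)."""

    label: str
    index: int
    per_barcode_seen: dict[str, int]
    per_barcode_passed: dict[str, int]
    kingdoms: dict[tuple[str, str], KingdomSnap]  # (barcode, kingdom) -> snap
    total_reads: int
    fraction_saturated: float
    stop: StopDecision


class RunProcessor:
    """Segregate, classify and accumulate reads batch by batch."""

    def __init__(self, config: MonitorConfig) -> None:
        self.config = config
        self.states: dict[tuple[str, Kingdom], AccumulationState] = {}
        self.profiles: dict[tuple[str, Kingdom], AbundanceProfile] = {}
        self.reads_seen: Counter = Counter()
        self.reads_passed: Counter = Counter()
        self.reject_reasons: Counter = Counter()
        self.unclassified_reads = 0
        self._snapshot_index = 0

    # -- per-batch pipeline -------------------------------------------------

    def process_batch(self, batch: ReadBatch) -> None:
        cfg = self.config
        barcode = batch.barcode
        if barcode == "unclassified":
            # counted, but excluded from all per-sample statistics
            self.unclassified_reads += len(batch)
            return
        self.reads_seen[barcode] += len(batch)
        per_kingdom: dict[Kingdom, list[ProcessedRead]] = {k: [] for k in cfg.models}
        for read in batch.reads:
            call = assign_kingdom(read, cfg.primer_sets, cfg.filter_params)
            if call.verdict.value == "unassigned":
                self.reject_reasons[call.reject_reason.value] += 1
                continue
            result = trim_and_filter(read, call, cfg.filter_params)
            if not isinstance(result, ProcessedRead):
                self.reject_reasons[result.reject_reason.value] += 1
                continue
            per_kingdom.setdefault(result.kingdom, []).append(result)

        for kingdom, model in cfg.models.items():
            reads = per_kingdom.get(kingdom, [])
            assignments = [
                classify_read(model, r.bases, read_seed(cfg.seed, r.read_id), r.read_id)
                for r in reads
            ]
            self.reads_passed[barcode] += len(reads)
            profile = profile_sample(
                assignments, model, sample_id=barcode, kingdom=kingdom
            )
            key = (barcode, kingdom)
            state = self.states.setdefault(key, AccumulationState(barcode, kingdom))
            update_accumulation(state, profile)
            if key in self.profiles:
                self.profiles[key] = self.profiles[key].merged_with(profile)
            else:
                self.profiles[key] = profile

    def process_file(self, path: Path | str) -> int:
        n = 0
        for batch in read_fastq_batches(
            [path], self.config.batch_size, self.config.layout
        ):
            self.process_batch(batch)
            n += len(batch)
        return n

    # -- snapshots ----------------------------------------------------------

    def stop_decision(self) -> StopDecision:
        return stop_recommendation(
            list(self.states.values()),
            self.config.sat_params,
            eligible_barcodes=self.config.sheet.subject_barcodes,
        )

    def snapshot(self, label: str = "") -> RunSnapshot:
        decision = self.stop_decision()
        kingdoms = {
            (bc, kd.value): KingdomSnap(
                reads=st.cumulative_reads,
                s_obs_history=tuple(st.s_obs_history),
                chao1_history=tuple(st.chao1_history),
                reads_history=tuple(st.reads_history),
                status=is_saturated(st, self.config.sat_params),
            )
            for (bc, kd), st in self.states.items()
        }
        snap = RunSnapshot(
            label=label or f"T{self._snapshot_index}",
            index=self._snapshot_index,
            per_barcode_seen=dict(self.reads_seen),
            per_barcode_passed=dict(self.reads_passed),
            kingdoms=kingdoms,
            total_reads=sum(self.reads_seen.values()) + self.unclassified_reads,
            fraction_saturated=decision.fraction_saturated,
            stop=decision,
        )
        self._snapshot_index += 1
        return snap

    def comparable_state(self) -> dict:
        """Order-insensitive digest of profiles and statuses, for equality
        checks between online and offline processing."""
        return {
            "profiles": {
                f"{bc}/{kd.value}": (
                    sorted(p.counts.items()),
                    p.unassigned,
                )
                for (bc, kd), p in sorted(self.profiles.items())
            },
            "statuses": {
                f"{bc}/{kd.value}": is_saturated(st, self.config.sat_params).value
                for (bc, kd), st in sorted(self.states.items())
            },
            "histories": {
                f"{bc}/{kd.value}": (
                    st.s_obs_history,
                    st.reads_history,
                )
                for (bc, kd), st in sorted(self.states.items())
            },
            "seen": dict(self.reads_seen),
            "passed": dict(self.reads_passed),
        }


# ---------------------------------------------------------------------------
# File discovery and the polling watcher
# ---------------------------------------------------------------------------


def _find_fastq_files(run_dir: Path, layout: str) -> list[Path]:
    if layout == "dir":
        root = run_dir / "fastq_pass"
        if not root.is_dir():
            root = run_dir
        files = [
            p
            for p in root.glob("*/*")
            if p.suffix in {".fastq", ".gz"} or p.name.endswith(".fastq.gz")
        ]
    else:
        files = [p for p in run_dir.iterdir() if p.name.endswith((".fastq", ".fastq.gz"))]
    return sorted(files, key=lambda p: (p.parent.name, p.name))


def _file_digest(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


class ProcessedLedger:
    """Persisted set of processed-file digests (crash-restart safety)."""

    def __init__(self, path: Path) -> None:
        self.path = Path(path)
        self._digests: dict[str, str] = {}
        if self.path.exists():
            self._digests = json.loads(self.path.read_text())

    def __contains__(self, digest: str) -> bool:
        return digest in self._digests

    def add(self, digest: str, filename: str) -> None:
        self._digests[digest] = filename
        self.path.parent.mkdir(parents=True, exist_ok=True)
        tmp = self.path.with_suffix(".tmp")
        tmp.write_text(json.dumps(self._digests, indent=0, sort_keys=True))
        tmp.replace(self.path)


def watch_run(
    run_dir: Path | str,
    config: MonitorConfig,
    poll_interval: float = 2.0,
    out_dir: Path | str | None = None,
    max_polls: Optional[int] = None,
    stop_on_decision: bool = False,
    processor: Optional[RunProcessor] = None,
) -> Iterator[RunSnapshot]:
    """Poll ``run_dir`` for completed FASTQ batch files and process each
    exactly once, yielding a snapshot after every processed file and a
    heartbeat snapshot on idle polls.

    A file is considered complete when its size is unchanged between two
    consecutive polls. Unreadable files are logged to the snapshot-free
    stderr path, skipped and retried on the next poll; the watcher itself
    never crashes on them. The generator ends after ``max_polls`` polls or,
    with ``stop_on_decision``, as soon as the stop rule fires.
    """
    run_dir = Path(run_dir)
    if not run_dir.is_dir():
        raise FileNotFoundError(run_dir)
    ledger_path = (
        Path(out_dir) / "processed_files.json"
        if out_dir is not None
        else run_dir / ".polyamp_processed.json"
    )
    ledger = ProcessedLedger(ledger_path)
    proc = processor if processor is not None else RunProcessor(config)
    sizes: dict[Path, int] = {}
    polls = 0
    while max_polls is None or polls < max_polls:
        polls += 1
        produced = False
        candidates = _find_fastq_files(run_dir, config.layout)
        stable: list[Path] = []
        new_sizes: dict[Path, int] = {}
        for path in candidates:
            try:
                size = path.stat().st_size
            except OSError:
                continue
            new_sizes[path] = size
            if sizes.get(path) == size:
                stable.append(path)
        sizes = new_sizes
        for path in stable:
            try:
                digest = _file_digest(path)
            except OSError:
                continue
            if digest in ledger:
                continue
            try:
                proc.process_file(path)
            except (OSError, ValueError):
                continue  # retried next poll
            ledger.add(digest, path.name)
            snap = proc.snapshot()
            produced = True
            yield snap
            if stop_on_decision and snap.stop.stop:
                return
        if not produced:
            yield proc.snapshot()
        if max_polls is None or polls < max_polls:
            time.sleep(poll_interval)


def process_run_offline(
    run_dir: Path | str, config: MonitorConfig, processor: Optional[RunProcessor] = None
) -> RunProcessor:
    """Process every batch file of a finished run in one deterministic pass
    (files sorted by barcode directory, then name)."""
    run_dir = Path(run_dir)
    proc = processor if processor is not None else RunProcessor(config)
    for path in _find_fastq_files(run_dir, config.layout):
        proc.process_file(path)
    return proc


# ---------------------------------------------------------------------------
# Snapshot reporting
# ---------------------------------------------------------------------------


def snapshot_report(snapshot: RunSnapshot, out_dir: Path | str) -> list[Path]:
    """Write plot-ready TSVs for one snapshot.

    ``status.tsv`` summarises per-(barcode, kingdom) reads and status;
    ``curves/<barcode>_<kingdom>.tsv`` holds the accumulation curve, one row
    per window labelled T0..Tk; ``run_log.tsv`` accumulates one line per
    snapshot with a strictly increasing index.
    """
    out_dir = Path(out_dir)
    (out_dir / "curves").mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    status_path = out_dir / "status.tsv"
    with open(status_path, "w") as out:
        out.write("barcode\tkingdom\treads\twindows\ts_obs\tchao1\tstatus\n")
        for (bc, kd), snap in sorted(snapshot.kingdoms.items()):
            s_obs = snap.s_obs_history[-1] if snap.s_obs_history else 0
            chao = snap.chao1_history[-1] if snap.chao1_history else 0.0
            out.write(
                f"{bc}\t{kd}\t{snap.reads}\t{len(snap.s_obs_history)}"
                f"\t{s_obs}\t{chao:.4f}\t{snap.status.value}\n"
            )
    written.append(status_path)

    for (bc, kd), snap in sorted(snapshot.kingdoms.items()):
        curve_path = out_dir / "curves" / f"{bc}_{kd}.tsv"
        with open(curve_path, "w") as out:
            out.write("window\tlabel\tcumulative_reads\ts_obs\tchao1\n")
            for w, (r, s, c) in enumerate(
                zip(snap.reads_history, snap.s_obs_history, snap.chao1_history)
            ):
                out.write(f"{w}\tT{w}\t{r}\t{s}\t{c:.4f}\n")
        written.append(curve_path)

    log_path = out_dir / "run_log.tsv"
    new = not log_path.exists()
    with open(log_path, "a") as out:
        if new:
            out.write(
                "index\tlabel\ttotal_reads\tfraction_saturated\tstop\n"
            )
        out.write(
            f"{snapshot.index}\t{snapshot.label}\t{snapshot.total_reads}"
            f"\t{snapshot.fraction_saturated:.4f}\t{int(snapshot.stop.stop)}\n"
        )
    written.append(log_path)
    return written
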