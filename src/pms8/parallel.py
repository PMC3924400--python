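"""Dynamic work-queue parallelism over first-sequence subproblems.

The search decomposes into m₁−l+1 independent subproblems, one per
window of the first sequence (the subproblem fixes that window as the
whole first sequence). Subproblem runtimes are highly uneven, so a
static split would leave workers starving; instead idle workers pull
the next job from a shared queue (here: a same-host process pool with
chunksize 1 — the scheduler/worker contract of the original
cluster design, without the cluster). Results are merged, deduplicated
and sorted, so the output is independent of completion order and of
the worker count, and equals the serial output.
"""

from __future__ import annotations

import multiprocessing as mp
from dataclasses import replace

from .instances import Instance
from .search import MotifResult, SearchParams, pms8_search

__all__ = ["split_jobs", "run_parallel_search"]


def split_jobs(instance: Instance, l: int) -> list[Instance]:
    """One subproblem per first-sequence window; union of outputs = serial."""
    first = instance.sequences[0]
    if len(first) < l:
        raise ValueError(f"l={l} exceeds the first sequence length")
    return [
        Instance([first[k : k + l]] + instance.sequences[1:], instance.alphabet)
        for k in range(len(first) - l + 1)
    ]


def _run_job(args) -> tuple[int, list[str] | None, dict]:
    k, job, l, d, params = args
    try:
        res = pms8_search(job, l, d, params)
        return k, res.motifs, res.stats
    except Exception:  # job is retried once by the driver
        return k, None, {}


def run_parallel_search(
    instance: Instance,
    l: int,
    d: int,
    params: SearchParams | None = None,
    workers: int = 1,
    with_positions: bool = False,
) -> MotifResult:
    """Run the search with ``workers`` processes pulling jobs dynamically.

    The merged, deduplicated, sorted motif set is identical to the
    serial search for any worker count. A failed job is re-queued once,
    then the error is raised.
    """
    if workers < 1:
        raise ValueError("workers must be >= 1")
    params = replace(params or SearchParams(), workers=1)
    jobs = split_jobs(instance, l)
    tasks = [(k, job, l, d, params) for k, job in enumerate(jobs)]

    motifs: set[str] = set()
    stats = {"tuples_explored": 0, "neighborhoods_generated": 0,
             "candidates_verified": 0, "jobs": len(jobs)}
    failed: list[int] = []

    def absorb(k: int, found: list[str] | None, st: dict) -> None:
        if found is None:
            failed.append(k)
            return
        motifs.update(found)
        for key in ("tuples_explored", "neighborhoods_generated",
                    "candidates_verified"):
            stats[key] += st.get(key, 0)

    if workers == 1:
        for task in tasks:
            absorb(*_run_job(task))
    else:
        ctx = mp.get_context("fork") if "fork" in mp.get_all_start_methods() \
            else mp.get_context()
        with ctx.Pool(processes=workers) as pool:
            # chunksize=1: each idle worker pulls the next job
            for k, found, st in pool.imap_unordered(_run_job, tasks, chunksize=1):
                absorb(k, found, st)

    # one retry for failed jobs, then hard error
    for k in list(failed):
        failed.remove(k)
        kk, found, st = _run_job(tasks[k])
        if found is None:
            raise RuntimeError(f"subproblem {k} failed twice")
        absorb(kk, found, st)

    sorted_motifs = sorted(motifs)
    positions = None
    if with_positions:
        from .search import _witness_positions

        positions = {m: _witness_positions(m, instance, l, d)
                     for m in sorted_motifs}
    return MotifResult(motifs=sorted_motifs, positions=positions, stats=stats)
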