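"""Regenerate the frozen expected values for the in-repo micro-fixture.

Everything here is computed by brute force — BFS connected components, and
explicit all-pairs Kronecker-delta loops for the enrichment fractions — kept
deliberately independent of the package's vectorized implementations. Run
from the repository root:

    python scripts/make_fixture_expected.py
"""

from __future__ import annotations

import json
from collections import deque
from pathlib import Path

from phyloprof.simulate import fixture_small

MIN_IDENTITY = 30.0


def brute_components(gene_ids, edges):
    adj = {g: set() for g in gene_ids}
    for a, b, pct, conf in edges:
        if pct >= MIN_IDENTITY and conf == "high":
            adj[a].add(b)
            adj[b].add(a)
    seen, comps = set(), []
    for g in sorted(gene_ids):
        if g in seen:
            continue
        comp, queue = set(), deque([g])
        while queue:
            x = queue.popleft()
            if x in comp:
                continue
            comp.add(x)
            queue.extend(adj[x] - comp)
        seen |= comp
        comps.append(sorted(comp))
    return comps


def brute_f_values(inside, outside):
    """(F_pw, F_all) by explicit pair enumeration over profile strings."""
    n = len(inside)
    within_pairs = ident_within = 0
    for i in range(n):
        for j in range(i + 1, n):
            within_pairs += 1
            ident_within += inside[i] == inside[j]
    cross_pairs = ident_cross = 0
    for p in inside:
        for q in outside:
            cross_pairs += 1
            ident_cross += p == q
    f_pw = ident_within / within_pairs if within_pairs else None
    denom = within_pairs + cross_pairs
    f_all = (ident_within + ident_cross) / denom if denom else None
    return f_pw, f_all


def main() -> None:
    bundle = fixture_small()
    ann = bundle.annotation
    gene_ids = list(ann["gene_id"])
    species_order = list(bundle.species["species_id"])
    species_of = dict(zip(ann["gene_id"], ann["species"]))
    maps_of = {
        g: [m for m in str(ms).split(";") if m]
        for g, ms in zip(ann["gene_id"], ann["maps"])
    }
    map_to_class = {}
    for ms, cs in zip(ann["maps"], ann["classes"]):
        for m, c in zip(str(ms).split(";"), str(cs).split(";")):
            if m:
                map_to_class[m] = c
    secondary = set(bundle.truth["secondary_classes"])

    edges = [
        (r.gene_a, r.gene_b, float(r.pct_identity), r.confidence)
        for r in bundle.homology.itertuples()
    ]
    comps = brute_components(gene_ids, edges)

    profiles = {}
    for k, members in enumerate(comps):
        bits = ["0"] * len(species_order)
        for g in members:
            bits[species_order.index(species_of[g])] = "1"
        profiles[k] = "".join(bits)

    # annotated objects only (all fixture genes are annotated)
    annotated = [k for k, members in enumerate(comps) if any(maps_of[g] for g in members)]

    def members_of(level_id, level):
        chosen = set()
        for k in annotated:
            for g in comps[k]:
                for m in maps_of[g]:
                    target_secondary = map_to_class[m] in secondary
                    gene_secondary = all(map_to_class[x] in secondary for x in maps_of[g])
                    if target_secondary and not gene_secondary:
                        continue
                    key = m if level == "map" else map_to_class[m]
                    if key == level_id:
                        chosen.add(k)
        return sorted(chosen)

    enrich = {}
    for level, ids in (("map", sorted(set(map_to_class))),
                       ("class", sorted(set(map_to_class.values())))):
        for pid in ids:
            mem = members_of(pid, level)
            inside = [profiles[k] for k in mem]
            outside = [profiles[k] for k in annotated if k not in set(mem)]
            f_pw, f_all = brute_f_values(inside, outside)
            e = None if (f_pw is None or not f_all) else f_pw / f_all
            enrich[f"{level}:{pid}"] = {
                "n_f": len(mem), "f_pw": f_pw, "f_all": f_all, "enrichment": e,
            }

    expected = {
        "n_objects": len(comps),
        "n_families": sum(1 for c in comps if len(c) > 1),
        "n_singletons": sum(1 for c in comps if len(c) == 1),
        "partition": {g: k for k, members in enumerate(comps) for g in members},
        "profiles": {str(k): profiles[k] for k in range(len(comps))},
        "n_unique_profiles": len(set(profiles.values())),
        "enrichment": enrich,
    }
    out = Path(__file__).resolve().parent.parent / "src" / "phyloprof" / "data"
    out.mkdir(parents=True, exist_ok=True)
    (out / "fixture_expected.json").write_text(json.dumps(expected, indent=2, sort_keys=True) + "\n")
    print(f"wrote {out / 'fixture_expected.json'}: {len(comps)} objects, "
          f"{len(enrich)} pathway entries")


if __name__ == "__main__":
    main()
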