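"""Independent brute-force classifier of dot-bracket elements.

A flat, scan-based reimplementation used to cross-check
``premir.fold.parse_anatomy``: no recursion, no chain bookkeeping — each
loop-closing pair is found and classified by direct scanning of the
partner array.
"""

from __future__ import annotations


def brute_anatomy(db: str) -> dict:
    n = len(db)
    partner = [-1] * n
    stack = []
    for i, c in enumerate(db):
        if c == "(":
            stack.append(i)
        elif c == ")":
            partner[i] = stack[-1]
            partner[stack.pop()] = i
    pairs = [(i, partner[i]) for i in range(n) if partner[i] > i]

    def direct_children(a: int, b: int) -> list[tuple[int, int]]:
        kids, k = [], a + 1
        while k < b:
            if partner[k] > k:
                kids.append((k, partner[k]))
                k = partner[k]
            k += 1
        return kids

    hairpins, bulges, syms, asyms, multiloop_nt = [], [], [], [], 0
    for a, b in pairs:
        kids = direct_children(a, b)
        unpaired_inside = (b - a - 1) - sum(q - p + 1 for p, q in kids)
        if not kids:
            hairpins.append(b - a - 1)
        elif len(kids) == 1:
            (p, q) = kids[0]
            left, right = p - a - 1, b - q - 1
            if left == 0 and right == 0:
                pass  # stacked pair, no loop
            elif left == 0 or right == 0:
                bulges.append(max(left, right))
            elif left == right:
                syms.append((left, right))
            else:
                asyms.append((left, right))
        else:
            multiloop_nt += unpaired_inside

    external = sum(
        1
        for i in range(n)
        if partner[i] < 0 and not any(a < i < b for a, b in pairs)
    )

    # helix runs by direct stacking check
    runs = []
    for a, b in pairs:
        if partner[a - 1] == b + 1 if a > 0 and b + 1 < n else False:
            continue  # not the outer end of a run
        ln, p, q = 1, a, b
        while p + 1 < q - 1 and partner[p + 1] == q - 1:
            ln += 1
            p, q = p + 1, q - 1
        runs.append(ln)

    # longest relaxed region: extend any run inward across symmetric loops
    def run_inner_end(a: int, b: int) -> tuple[int, int, int]:
        ln, p, q = 1, a, b
        while p + 1 < q - 1 and partner[p + 1] == q - 1:
            ln += 1
            p, q = p + 1, q - 1
        return ln, p, q

    outer_run_starts = [
        (a, b)
        for a, b in pairs
        if not (a > 0 and b + 1 < n and partner[a - 1] == b + 1)
    ]
    l_rsym = 0
    for a, b in outer_run_starts:
        total = 0
        cur = (a, b)
        while cur is not None:
            ln, p, q = run_inner_end(*cur)
            total += ln
            kids = direct_children(p, q)
            cur = None
            if len(kids) == 1:
                (c, d) = kids[0]
                left, right = c - p - 1, q - d - 1
                if left == right and left > 0:
                    cur = (c, d)
        l_rsym = max(l_rsym, total)

    return {
        "n_hairpin_loops": len(hairpins),
        "hairpin_loop_lens": sorted(hairpins),
        "bulges": sorted(bulges),
        "sym_loops": sorted(syms),
        "asym_loops": sorted(asyms),
        "n_base_pairs": len(pairs),
        "external_nt": external,
        "multiloop_nt": multiloop_nt,
        "helix_runs": sorted(runs),
        "l_sym_rgn": max(runs, default=0),
        "l_rsym_rgn": l_rsym,
        "stem_region_nt": 2 * len(pairs)
        + sum(bulges)
        + sum(l + r for l, r in syms + asyms),
    }


def enumerate_balanced(max_len: int) -> list[str]:
    """All balanced dot-bracket strings of length <= max_len."""
    cache: dict[int, tuple[str, ...]] = {0: ("",)}

    def gen(n: int) -> tuple[str, ...]:
        if n not in cache:
            out = ["." + s for s in gen(n - 1)]
            for k in range(n - 1):
                for a in gen(k):
                    for b in gen(n - 2 - k):
                        out.append("(" + a + ")" + b)
            cache[n] = tuple(out)
        return cache[n]

    result: list[str] = []
    for n in range(max_len + 1):
        result.extend(gen(n))
    return result
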