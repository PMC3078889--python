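"""Jitted event loops for the serial structured coalescent.

Time runs backwards, is continuous, and is measured in generations before
present.  Deme codes: 0 = crossriver, 1 = western.  The Cross River deme
shrinks forward-in-time exponentially from ``n_cr_now * ratio`` at
``t_bottleneck`` to ``n_cr_now`` today, i.e. backwards the size is
``n_cr_now * exp(beta * t)`` on [0, t_bottleneck] and constant
``n_cr_now * ratio`` from there to the divergence time, at which all lineages
merge into a single ancestral deme of size ``n_ancestral``.

The inhomogeneous rates of the exponential epoch are handled by thinning: the
total event rate is non-increasing backwards within every epoch, so proposals
drawn at the epoch-entry rate and accepted with probability rate(t)/rate_max
are exact.  No per-generation discretization is used.
"""

import numpy as np
from numba import njit

#: sentinel for "no parent" (the root)
NO_PARENT = -1

_MAX_ITER = 100_000_000


@njit(cache=True)
def genealogy_kernel(
    seed,
    samp_times,   # float64[:] ascending sampling times per group
    samp_demes,   # int64[:]   deme per group
    samp_counts,  # int64[:]   haploid sample size per group
    n_cr_now, ratio, t_bot, n_w, n_anc, t_div,
    model_im,     # True: isolation-with-migration; False: secondary admixture
    two_nm, t_mig, t_adm, gamma,
):
    """Simulate one genealogy; returns (parent, node_time) arrays.

    Leaves are numbered group by group in the order given (0..n-1); internal
    nodes follow in coalescence order; the root has parent NO_PARENT.
    """
    np.random.seed(seed)
    n = 0
    for i in range(samp_counts.size):
        n += samp_counts[i]
    n_nodes = 2 * n - 1
    parent = np.full(n_nodes, NO_PARENT, dtype=np.int64)
    node_time = np.zeros(n_nodes, dtype=np.float64)

    # leaf id ranges per group
    first_leaf = np.zeros(samp_counts.size, dtype=np.int64)
    acc = 0
    for i in range(samp_counts.size):
        first_leaf[i] = acc
        acc += samp_counts[i]
        for j in range(first_leaf[i], acc):
            node_time[j] = samp_times[i]

    active_node = np.empty(n, dtype=np.int64)
    active_deme = np.empty(n, dtype=np.int64)
    k = 0                     # active lineages
    next_internal = n
    ptr = 0                   # next pending sample group
    t = samp_times[0]
    merged = False
    adm_done = False

    beta = 0.0
    if ratio > 1.0 and t_bot > 0.0:
        beta = np.log(ratio) / t_bot

    it = 0
    while it < _MAX_ITER:
        it += 1

        # --- boundary side effects at the current time -------------------
        while ptr < samp_counts.size and samp_times[ptr] <= t:
            d = samp_demes[ptr]
            for j in range(first_leaf[ptr], first_leaf[ptr] + samp_counts[ptr]):
                active_node[k] = j
                active_deme[k] = 0 if merged else d
                k += 1
            ptr += 1
        if (not model_im) and (not adm_done) and (not merged) and t >= t_adm:
            # secondary-admixture pulse: backwards, each Cross River lineage
            # traces to a western immigrant with probability gamma
            for i in range(k):
                if active_deme[i] == 0 and np.random.random() < gamma:
                    active_deme[i] = 1
            adm_done = True
        if (not merged) and t >= t_div:
            merged = True
            for i in range(k):
                active_deme[i] = 0

        if k == 1 and ptr >= samp_counts.size:
            break

        # --- deme occupancies and rates ----------------------------------
        k_cr = 0
        for i in range(k):
            if active_deme[i] == 0:
                k_cr += 1
        k_w = k - k_cr

        mig_on = model_im and (not merged) and t >= t_mig and two_nm > 0.0

        # next deterministic boundary strictly ahead of t
        tb = np.inf
        if ptr < samp_counts.size and samp_times[ptr] < tb:
            tb = samp_times[ptr]
        if not merged:
            if t < t_bot and t_bot < tb:
                tb = t_bot
            if model_im and t < t_mig and t_mig < tb:
                tb = t_mig
            if (not model_im) and (not adm_done) and t < t_adm and t_adm < tb:
                tb = t_adm
            if t_div < tb:
                tb = t_div

        if merged:
            q_cr = k * (k - 1) / 4.0
            n_cr_t = n_anc
            q_w = 0.0
        else:
            q_cr = k_cr * (k_cr - 1) / 4.0
            q_w = k_w * (k_w - 1) / 4.0
            if mig_on:
                q_cr += k_cr * two_nm / 2.0
                q_w += k_w * two_nm / 2.0
            if t < t_bot:
                n_cr_t = n_cr_now * np.exp(beta * t)
            else:
                n_cr_t = n_cr_now * ratio

        rate_max = q_cr / n_cr_t + q_w / n_w

        if rate_max <= 0.0:
            # nothing can happen until the next boundary
            t = tb
            continue

        t_cand = t + np.random.exponential(1.0 / rate_max)
        if t_cand >= tb:
            t = tb
            continue

        # thinning acceptance; only the CR size varies within an epoch
        if merged:
            n_cr_cand = n_anc
        elif t_cand < t_bot:
            n_cr_cand = n_cr_now * np.exp(beta * t_cand)
        else:
            n_cr_cand = n_cr_now * ratio
        rate_cr = q_cr / n_cr_cand
        rate_w = q_w / n_w
        rate_now = rate_cr + rate_w
        if np.random.random() > rate_now / rate_max:
            t = t_cand
            continue

        # --- an event happens at t_cand ----------------------------------
        t = t_cand
        u = np.random.random() * rate_now
        coal_cr = (q_cr if merged else k_cr * (k_cr - 1) / 4.0) / n_cr_cand
        coal_w = 0.0 if merged else (k_w * (k_w - 1) / 4.0) / n_w
        mig_cr = rate_cr - coal_cr
        if u < coal_cr:
            do_coal, event_deme = True, 0
        elif u < coal_cr + coal_w:
            do_coal, event_deme = True, 1
        elif u < coal_cr + coal_w + mig_cr:
            do_coal, event_deme = False, 0
        else:
            do_coal, event_deme = False, 1

        if do_coal:
            kd = k if merged else (k_cr if event_deme == 0 else k_w)
            i1 = int(np.random.random() * kd)
            i2 = int(np.random.random() * (kd - 1))
            if i2 >= i1:
                i2 += 1
            a1 = -1
            a2 = -1
            seen = 0
            for i in range(k):
                if merged or active_deme[i] == event_deme:
                    if seen == i1:
                        a1 = i
                    if seen == i2:
                        a2 = i
                    seen += 1
            node = next_internal
            next_internal += 1
            node_time[node] = t
            parent[active_node[a1]] = node
            parent[active_node[a2]] = node
            lo = a1 if a1 < a2 else a2
            hi = a2 if a1 < a2 else a1
            active_node[lo] = node
            active_deme[lo] = event_deme if not merged else 0
            active_node[hi] = active_node[k - 1]
            active_deme[hi] = active_deme[k - 1]
            k -= 1
        else:
            kd = k_cr if event_deme == 0 else k_w
            pick = int(np.random.random() * kd)
            seen = 0
            for i in range(k):
                if active_deme[i] == event_deme:
                    if seen == pick:
                        active_deme[i] = 1 - event_deme
                        break
                    seen += 1

    if k != 1:
        raise RuntimeError("event budget exhausted; genealogy did not coalesce")
    return parent, node_time


@njit(cache=True)
def mutate_kernel(seed, parent, node_time, mu, root_size):
    """Drop stepwise mutations on a genealogy.

    Per branch the mutation count is Poisson(mu * branch length); each step is
    +1 or -1 repeat with probability 1/2.  Returns integer allele sizes for
    all nodes; callers slice out the leaves.
    """
    np.random.seed(seed)
    n_nodes = parent.size
    alleles = np.empty(n_nodes, dtype=np.int64)
    order = np.argsort(node_time)
    # parents are always older than children, so walking nodes from the
    # oldest to the youngest processes every parent first
    for idx in range(n_nodes - 1, -1, -1):
        node = order[idx]
        par = parent[node]
        if par == NO_PARENT:
            alleles[node] = root_size
        else:
            lam = mu * (node_time[par] - node_time[node])
            nm = np.random.poisson(lam)
            if nm > 0:
                step = 2 * np.random.binomial(nm, 0.5) - nm
            else:
                step = 0
            alleles[node] = alleles[par] + step
    return alleles
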