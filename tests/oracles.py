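"""Independent oracles used by the test suite.

The path-enumeration likelihood below is written directly from the
model's verbal description (hand-built transition tables, recursive
enumeration over every latent state path) and deliberately shares no
code with the package's forward recursion.
"""

from scipy.special import expit, logit


def enumerate_word_likelihood(params, recalls, offsets=(0.0, 0.0, 0.0)):
    """Marginal probability of a 4-slot recall pattern by brute-force
    enumeration of all latent storage-state paths (<= 3^4 effective).

    ``params`` is the 7-vector (N1, N2, N3, N4, R1, R2, R3);
    ``recalls`` the observed pattern (IFR1, IFR2, IFR3, DFR);
    ``offsets`` the logit adjustments at the three presentations.
    """
    n1_, n2_, n3, n4, r1, r2, r3 = [float(x) for x in params]
    P, T, D = "P", "T", "D"

    def present(state, off):
        if state == P:
            n1 = expit(logit(n1_) + off) if off else n1_
            n2 = expit(logit(n2_) + off) if off else n2_
            return {D: n1, T: (1 - n1) * n2, P: (1 - n1) * (1 - n2)}
        if state == T:
            return {D: n3, T: 1 - n3}
        return {D: 1.0}

    def emission(state, task):
        if state == T and task == "IFR":
            return r1
        if state == D:
            return r2 if task == "IFR" else r3
        return 0.0

    def after_recall(state, recalled):
        if state == T and recalled:
            return {D: n4, T: 1 - n4}
        return {state: 1.0}

    total = 0.0

    def walk(task, state, prob):
        nonlocal total
        if prob == 0.0:
            return
        if task == 3:
            e = emission(state, "DFR")
            total += prob * (e if recalls[3] else 1.0 - e)
            return
        for s_pres, p_pres in present(state, offsets[task]).items():
            e = emission(s_pres, "IFR")
            p_obs = e if recalls[task] else 1.0 - e
            if p_obs == 0.0:
                continue
            for s_post, p_post in after_recall(s_pres, recalls[task]).items():
                walk(task + 1, s_post, prob * p_pres * p_obs * p_post)

    walk(0, P, 1.0)
    return total
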