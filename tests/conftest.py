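import numpy as np
import pytest

from famliab import Individual, Pedigree, Sex


@pytest.fixture
def trio() -> Pedigree:
    """Index child with two founder parents."""
    return Pedigree(
        [
            Individual("child", "father", "mother", Sex.MALE, is_index=True),
            Individual("father", sex=Sex.MALE),
            Individual("mother", sex=Sex.FEMALE),
        ]
    )


@pytest.fixture
def nuclear5() -> Pedigree:
    """Index child with two parents and two full siblings."""
    return Pedigree(
        [
            Individual("c1", "fa", "mo", Sex.FEMALE, is_index=True),
            Individual("fa", sex=Sex.MALE),
            Individual("mo", sex=Sex.FEMALE),
            Individual("c2", "fa", "mo", Sex.MALE),
            Individual("c3", "fa", "mo", Sex.FEMALE),
        ]
    )


@pytest.fixture
def two_generation8() -> Pedigree:
    """Grandparents, father + uncle, founder mother, index + sibling + first cousin's parent line.

    gpa x gma -> fa, uncle; fa x mo -> index, sib. Eight members spanning
    grandparental, parental, and index generations.
    """
    return Pedigree(
        [
            Individual("index", "fa", "mo", Sex.MALE, is_index=True),
            Individual("sib", "fa", "mo", Sex.FEMALE),
            Individual("fa", "gpa", "gma", Sex.MALE),
            Individual("uncle", "gpa", "gma", Sex.MALE),
            Individual("mo", sex=Sex.FEMALE),
            Individual("gpa", sex=Sex.MALE),
            Individual("gma", sex=Sex.FEMALE),
            Individual("aunt", "gpa", "gma", Sex.FEMALE),
        ]
    )


def gene_drop_relationship(ped: Pedigree, n_rep: int, seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Monte-Carlo additive relationship estimate by dropping allele labels.

    Founders receive unique allele labels; each child inherits one random
    allele from each parent. The per-replicate coefficient for a pair is
    twice the kinship: half the mean IBD-indicator over the four
    allele-pair choices. Returns (estimate, standard error), both (n, n).
    """
    rng = np.random.default_rng(seed)
    n = ped.n
    pos = {ind.id: i for i, ind in enumerate(ped.individuals)}
    order = ped._topological_order()
    alleles = np.zeros((n, 2, n_rep), dtype=np.int64)
    next_label = 1
    for i in order:
        ind = ped.individuals[i]
        for slot, pid in enumerate((ind.father_id, ind.mother_id)):
            if pid is None or pid not in pos:
                alleles[i, slot] = next_label
                next_label += 1
            else:
                p = pos[pid]
                pick = rng.integers(0, 2, size=n_rep)
                alleles[i, slot] = alleles[p][pick, np.arange(n_rep)]
    est = np.zeros((n, n))
    se = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            share = np.zeros(n_rep)
            for a in range(2):
                for b in range(2):
                    share += alleles[i, a] == alleles[j, b]
            coeff = share / 2.0  # 2 * kinship per replicate
            est[i, j] = coeff.mean()
            se[i, j] = coeff.std(ddof=1) / np.sqrt(n_rep)
    return est, se


def auc_se(a: float, n_case: int, n_ctrl: int) -> float:
    """Hanley-McNeil standard error of an empirical AUC."""
    q1 = a / (2 - a)
    q2 = 2 * a**2 / (1 + a)
    var = (a * (1 - a) + (n_case - 1) * (q1 - a**2) + (n_ctrl - 1) * (q2 - a**2)) / (
        n_case * n_ctrl
    )
    return float(np.sqrt(max(var, 0.0)))
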