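import itertools
from types import SimpleNamespace

import pytest

from eif2btools import synthetic
from eif2btools.structure_io import assign_subunits, load_structure


@pytest.fixture(scope="session")
def decamer(tmp_path_factory):
    """Default toy decamer fixture, loaded back through the real parser."""
    directory = tmp_path_factory.mktemp("decamer")
    path, info = synthetic.make_decamer_fixture(synthetic.DEFAULT_SEED, directory)
    model = load_structure(path)
    assignment = assign_subunits(model, info.reference_library)
    return SimpleNamespace(path=path, dir=directory, info=info, model=model,
                           assignment=assignment)


@pytest.fixture()
def perturb(decamer, tmp_path):
    """Factory: apply motions to the session fixture, reload, assign."""
    counter = itertools.count()

    def _perturb(motions, entry_id="PERT"):
        out = tmp_path / f"perturbed_{next(counter)}.cif"
        path, ledger = synthetic.perturb_fixture(
            decamer.path, motions, out, info=decamer.info, entry_id=entry_id)
        model = load_structure(path)
        assignment = assign_subunits(model, decamer.info.reference_library)
        return SimpleNamespace(path=path, model=model, assignment=assignment,
                               ledger=ledger)

    return _perturb
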