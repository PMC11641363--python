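import numpy as np
import pytest

from enhancerrl.config import desk_preset
from enhancerrl.network import NetworkConfig
from enhancerrl.ppo import PpoHyperparams
from enhancerrl.sequence_io import split_dataset
from enhancerrl.synthetic import SynthConfig, generate
from enhancerrl.training import TrainConfig, Trainer


@pytest.fixture
def tiny_records():
    """40 short balanced records for fast unit tests."""
    return generate(SynthConfig(n_pos=20, n_neg=20, length=60, seed=7))


def tiny_trainer_config(**overrides):
    """A very small but structurally complete configuration."""
    net = NetworkConfig(embed_dim=16, resnet_out_dim=8, transformer_out_dim=8,
                        n_heads=2, n_encoder_blocks=1,
                        resnet_width_factor=0.1, kernel=3)
    defaults = dict(batch_size=16, epochs_phase1=2, epochs_phase2=2,
                    epochs_phase3=2, seed=11, l_max=30)
    defaults.update(overrides)
    return net, TrainConfig(**defaults)


@pytest.fixture
def tiny_trainer(tiny_records):
    split = split_dataset(tiny_records, 0.2, 3)
    net, cfg = tiny_trainer_config()
    return Trainer(split.train, split.validation, net, cfg, PpoHyperparams())


@pytest.fixture(scope="session")
def study_data():
    """The synthetic study conditions: 500+500 train, 100+100 test, 200 bp,
    GC 0.6 vs 0.4, planted CpG-rich motif."""
    cfg = desk_preset(seed=42)
    train = generate(cfg.synth)
    test_cfg = SynthConfig(n_pos=100, n_neg=100, seed=cfg.synth.seed + 1)
    return train, generate(test_cfg)


@pytest.fixture(scope="session")
def fitted_pipeline(study_data):
    """One full three-phase fit on the study fixture, shared across tests."""
    train, _ = study_data
    cfg = desk_preset(seed=42)
    split = split_dataset(train, cfg.split_fraction, cfg.split_seed)
    trainer = Trainer(split.train, split.validation, cfg.network, cfg.train,
                      cfg.ppo)
    trainer.fit()
    return trainer
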