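"""Contrastive (CLIP-objective) training of the dual encoder.

One random frame per video per epoch pairs with the study's tokenized
report; the symmetric InfoNCE loss over in-batch negatives aligns the two
towers. The learning rate ramps linearly over a warmup and cosine-decays to
zero; the checkpoint with the lowest validation mean cross-modal retrieval
rank (MCMRR) is returned. Splits must be disjoint at the patient level —
studies of one patient are highly correlated, so a study-level split would
leak.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .encoders import (DualEncoder, EncoderConfig, normalize_frames,
                       pooled_normalized_frames, pack_token_batch)
from .nn import Tensor, no_grad, AdamW
from .retrieval import evaluate_retrieval
from .synthetic import PairedStudyRecord, stable_hash32, video_uid
from .tokenizer import TemplateVocabulary, TokenSequence, tokenize

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TrainConfig:
    batch_size: int = 32
    epochs: int = 30
    peak_lr: float = 1e-3
    warmup_steps: int = 20
    seed: int = 0
    weight_decay: float = 0.2
    permute_pairs: bool = False  # control: destroy image-text correspondence
    # text augmentation: with probability snippet_prob a training pair uses a
    # random contiguous report snippet of snippet_sentences whole sentences
    # instead of the full (truncated) report; mirrors snippet-based training
    # of short-context report encoders and stops the image tower from
    # ignoring attributes that rarer snippets isolate
    snippet_prob: float = 0.3
    snippet_sentences: tuple[int, int] = (1, 4)
    # weight of the value-alignment loss term: every step adds a second
    # symmetric InfoNCE over the same image batch against each study's
    # single number-bearing sentence, the desk-scale surrogate for the
    # large-batch regime where near-duplicate attribute profiles force the
    # model to break ties on numeric values. Running it alongside (not
    # instead of) the whole-report loss keeps retrieval at full strength
    # while denying the report loss any window to suppress the numeric
    # correlate; 0 disables the term. The default weight is deliberately
    # high: the numeric correlate is the weakest visual signal and loses
    # the capacity competition at low weights
    value_loss_weight: float = 8.0
    # restrict value-aligned batches to these canonical template forms; None
    # allows every number-bearing template shared by all training reports.
    # Only templates whose number has a pixel correlate are useful here —
    # batches built on a visually silent quantity are pure label noise, so
    # the default is the ejection-fraction sentence of the built-in grammar
    value_batch_templates: tuple[str, ...] | None = (
        "Left ventricular ejection fraction is _%.",)

    def __post_init__(self):
        if self.batch_size < 2:
            raise ValueError("batch_size must be >= 2")
        if self.value_loss_weight < 0:
            raise ValueError("value_loss_weight must be >= 0")
        if self.warmup_steps < 0 or self.epochs < 0:
            raise ValueError("warmup_steps and epochs must be >= 0")
        if self.peak_lr <= 0:
            raise ValueError("peak_lr must be positive")


def clip_loss(image_embs: np.ndarray, text_embs: np.ndarray,
              temperature: float) -> float:
    """Symmetric InfoNCE on unit-norm embeddings.

    Logits are the N x N cosine-similarity matrix divided by ``temperature``;
    the loss is the mean of the row-wise and column-wise cross-entropies with
    the matched pairs (the diagonal) as targets. Equals ln(N) when all
    logits are equal; 0 for a single pair.
    """
    img = np.asarray(image_embs, dtype=np.float64)
    txt = np.asarray(text_embs, dtype=np.float64)
    if img.ndim != 2 or txt.shape != img.shape:
        raise ValueError("need matching (N, D) embedding arrays")
    n = len(img)
    if n == 0:
        raise ValueError("empty batch")
    if not (np.isfinite(img).all() and np.isfinite(txt).all()):
        raise ValueError("non-finite embeddings")
    logits = (img @ txt.T) / float(temperature)

    def ce(mat, axis):
        z = mat - mat.max(axis=axis, keepdims=True)
        logp = z - np.log(np.exp(z).sum(axis=axis, keepdims=True))
        return -np.mean(np.diagonal(logp))

    return float((ce(logits, 1) + ce(logits, 0)) / 2.0)


def clip_loss_tensor(img: Tensor, txt: Tensor, scale: Tensor) -> Tensor:
    """Differentiable counterpart of :func:`clip_loss`, with logits scaled by
    ``scale`` (= 1/temperature)."""
    logits = (img @ txt.transpose(1, 0)) * scale
    n = logits.shape[0]
    diag = (np.arange(n), np.arange(n))
    row = logits.log_softmax(axis=1)[diag].mean()
    col = logits.log_softmax(axis=0)[diag].mean()
    return (row + col) * (-0.5)


def lr_schedule(step: int, config: TrainConfig, total_steps: int) -> float:
    """Linear warmup to peak_lr, then cosine decay to zero at total_steps."""
    if total_steps <= config.warmup_steps:
        raise ValueError("total_steps must exceed warmup_steps")
    if not 0 <= step <= total_steps:
        raise ValueError(f"step {step} outside [0, {total_steps}]")
    if step < config.warmup_steps:
        return config.peak_lr * step / config.warmup_steps
    progress = (step - config.warmup_steps) / (total_steps - config.warmup_steps)
    return config.peak_lr * 0.5 * (1.0 + np.cos(np.pi * progress))


def sample_training_frame(video: np.ndarray, epoch: int, seed: int,
                          video_id: str = "") -> int:
    """Uniform random frame index, reproducible from (seed, epoch, video id);
    a fresh frame per epoch acts as data augmentation."""
    T = video.shape[0]
    if T < 1:
        raise ValueError("empty video")
    rng = np.random.default_rng([np.uint32(seed), np.uint32(epoch),
                                 np.uint32(stable_hash32(video_id))])
    return int(rng.integers(T))


@dataclass
class TrainResult:
    model: DualEncoder
    best_epoch: int
    metrics: list[dict] = field(default_factory=list)  # epoch, loss, val_mcmrr, lr


def check_patient_split(train_records, val_records):
    overlap = ({r.patient_id for r in train_records}
               & {r.patient_id for r in val_records})
    if overlap:
        raise ValueError(f"patient overlap between splits: {sorted(overlap)[:5]}")


def _study_text_embs(model: DualEncoder, seqs: list[TokenSequence]) -> np.ndarray:
    # batch in chunks to bound attention memory
    outs = [model.encode_text(seqs[i:i + 64]) for i in range(0, len(seqs), 64)]
    return np.concatenate(outs, axis=0)


def validation_mcmrr(model: DualEncoder, val_records: list[PairedStudyRecord],
                     seed: int) -> float:
    """MCMRR over the validation studies, one random video per study and one
    random frame per chosen video, both fixed by ``seed``."""
    rng = np.random.default_rng(np.uint32(seed))
    frames, seqs = [], []
    for r in val_records:
        v = r.videos[int(rng.integers(len(r.videos)))]
        frames.append(v[int(rng.integers(v.shape[0]))])
        seqs.append(tokenize(r.report_text, model.vocab))
    img = np.concatenate([model.encode_image(np.stack(frames[i:i + 64]))
                          for i in range(0, len(frames), 64)], axis=0)
    txt = _study_text_embs(model, seqs)
    return evaluate_retrieval(img, txt).mcmrr


def train(train_records: list[PairedStudyRecord],
          val_records: list[PairedStudyRecord],
          enc_config: EncoderConfig | None = None,
          train_config: TrainConfig | None = None,
          vocab: TemplateVocabulary | None = None) -> TrainResult:
    """Train a dual encoder on paired study records.

    Returns the checkpoint from the epoch with the lowest validation MCMRR,
    together with the per-epoch metrics log.
    """
    enc_config = enc_config or EncoderConfig()
    cfg = train_config or TrainConfig()
    check_patient_split(train_records, val_records)
    if vocab is None:
        from .synthetic import default_grammar
        vocab = default_grammar()
    model = DualEncoder(enc_config, vocab, seed=cfg.seed)

    # training items: (record index, video index); text cached per study
    items = [(ri, vi) for ri, r in enumerate(train_records)
             for vi in range(len(r.videos))]
    seqs = [tokenize(r.report_text, vocab) for r in train_records]

    rng = np.random.default_rng(np.uint32(cfg.seed))
    if cfg.permute_pairs:
        # pairing control: each video trains against a shuffled study's text
        text_of = rng.permutation(len(train_records))
    else:
        text_of = np.arange(len(train_records))

    number_windows = [_number_sentence_windows(s) for s in seqs]
    shared_number_tids = (set.intersection(*(set(w) for w in number_windows))
                          if number_windows else set())
    if cfg.value_batch_templates is not None:
        allowed = {e.template_id for e in vocab.entries
                   if e.canonical_form in cfg.value_batch_templates}
        if not allowed:
            logger.warning("no value_batch_templates found in the vocabulary; "
                           "value steps disabled")
        shared_number_tids &= allowed
    value_tids = sorted(shared_number_tids)

    steps_per_epoch = max(len(items) // cfg.batch_size, 1)
    total_steps = max(cfg.epochs * steps_per_epoch, cfg.warmup_steps + 1)
    opt = AdamW(model.parameters(), lr=cfg.peak_lr,
                weight_decay=cfg.weight_decay)

    use_value_loss = bool(value_tids) and cfg.value_loss_weight > 0

    metrics: list[dict] = []
    best = (np.inf, -1, model.state_dict())
    step = 0
    for epoch in range(cfg.epochs):
        order = rng.permutation(len(items))
        losses = []
        for b in range(steps_per_epoch):
            chunk = order[b * cfg.batch_size:(b + 1) * cfg.batch_size]
            if len(chunk) < 2:
                continue
            # one number-bearing template per step for the value-loss views
            tid = (value_tids[int(rng.integers(len(value_tids)))]
                   if use_value_loss else None)
            frames, batch_seqs, value_seqs = [], [], []
            for j in chunk:
                ri, vi = items[j]
                video = train_records[ri].videos[vi]
                fi = sample_training_frame(video, epoch, cfg.seed,
                                           video_uid(train_records[ri], vi))
                frames.append(video[fi])
                batch_seqs.append(_train_view(seqs[text_of[ri]],
                                              enc_config.text_context_length,
                                              cfg, rng))
                if tid is not None:
                    value_seqs.append(number_windows[text_of[ri]][tid])
            batch = np.stack(frames)
            if enc_config.image_arch == "small_convnet" and batch.dtype == np.uint8:
                x = Tensor(pooled_normalized_frames(batch))
            else:
                x = Tensor(normalize_frames(batch))
            ids, values, last_idx = pack_token_batch(
                batch_seqs, enc_config.text_context_length)
            img = model.image_forward(x)
            txt = model.text_forward(ids, values, last_idx)
            loss = clip_loss_tensor(img, txt, model.logit_scale())
            if tid is not None:
                v_ids, v_values, v_last = pack_token_batch(
                    value_seqs, enc_config.text_context_length)
                v_txt = model.text_forward(v_ids, v_values, v_last)
                v_loss = clip_loss_tensor(img, v_txt, model.logit_scale())
                loss = loss + v_loss * cfg.value_loss_weight
            model.zero_grad()
            loss.backward()
            opt.lr = lr_schedule(step, cfg, total_steps)
            opt.step()
            step += 1
            losses.append(loss.item())
        val = validation_mcmrr(model, val_records, seed=cfg.seed)
        metrics.append({"epoch": epoch, "loss": float(np.mean(losses)) if losses else np.nan,
                        "val_mcmrr": val, "lr": opt.lr,
                        "logit_scale": float(np.exp(model.log_scale.data[0]))})
        logger.info("epoch %d loss %.4f val_mcmrr %.2f lr %.2e",
                    epoch, metrics[-1]["loss"], val, opt.lr)
        if val < best[0]:
            best = (val, epoch, model.state_dict())
    if best[1] >= 0:
        model.load_state_dict(best[2])
    return TrainResult(model=model, best_epoch=best[1], metrics=metrics)


def _number_sentence_windows(seq: TokenSequence) -> dict[int, TokenSequence]:
    """template_id -> single-sentence window, for sentences carrying a
    NUMBER slot (first occurrence per template)."""
    from .tokenizer import NUM_ID, TEMPLATE_OFFSET

    out: dict[int, TokenSequence] = {}
    starts = [i for i, t in enumerate(seq.tokens) if t >= TEMPLATE_OFFSET]
    for k, i in enumerate(starts):
        stop = starts[k + 1] if k + 1 < len(starts) else seq.length
        # UNK tokens break sentence runs; restrict to this template's span
        if NUM_ID in seq.tokens[i:stop] and seq.tokens[i] not in out:
            out[seq.tokens[i]] = seq.window(i, stop - i)
    return out


def _train_view(seq: TokenSequence, context: int, cfg: TrainConfig,
                rng: np.random.Generator) -> TokenSequence:
    """Training view of a report: with probability ``snippet_prob`` a random
    contiguous run of whole sentences, otherwise the full sequence (windowed
    randomly if it exceeds the context length)."""
    from .tokenizer import TEMPLATE_OFFSET, UNK_ID

    if cfg.snippet_prob > 0 and rng.random() < cfg.snippet_prob:
        starts = [i for i, t in enumerate(seq.tokens)
                  if t >= TEMPLATE_OFFSET or t == UNK_ID]
        n_sent = int(rng.integers(cfg.snippet_sentences[0],
                                  cfg.snippet_sentences[1] + 1))
        n_sent = min(n_sent, len(starts))
        first = int(rng.integers(0, len(starts) - n_sent + 1))
        stop = (starts[first + n_sent] if first + n_sent < len(starts)
                else seq.length)
        view = seq.window(starts[first], stop - starts[first])
        if view.length:
            return view.truncate(context)
    if seq.length <= context:
        return seq
    start = int(rng.integers(0, seq.length - context + 1))
    return seq.window(start, context)


__all__ = ["TrainConfig", "TrainResult", "clip_loss", "clip_loss_tensor",
           "lr_schedule", "sample_training_frame", "train", "validation_mcmrr",
           "check_patient_split"]
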