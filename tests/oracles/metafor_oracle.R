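library(metafor)
d <- read.csv("metafor_fixture.csv")
d$obs <- seq_len(nrow(d))
# intercept-only, random study/trait/taxon
m1 <- rma.mv(y, v, random = list(~1|study, ~1|trait, ~1|taxon), data=d, method="REML",
             control=list(optimizer="optim", optmethod="BFGS"))
cat("m1 beta", coef(m1), "se", m1$se, "\n")
cat("m1 sigma2", m1$sigma2, "\n")
cat("m1 ll", logLik(m1), "\n")
# moderated sex*env with obs-level
d$sex <- relevel(factor(d$sex), ref="male")
d$env <- relevel(factor(d$env), ref="benign")
m2 <- rma.mv(y, v, mods=~sex*env, random = list(~1|study, ~1|obs), data=d, method="REML",
             control=list(optimizer="optim", optmethod="BFGS"))
cat("m2 beta", coef(m2), "\n")
cat("m2 se", m2$se, "\n")
cat("m2 sigma2", m2$sigma2, "\n")
cat("m2 ll", logLik(m2), "\n")
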