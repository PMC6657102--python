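# English stop words, version 1.
# One token per line; '#' lines are comments.  The feature space removes the
# negation tokens (neither, never, no, nor, not) from this list at load time
# so they remain available as classification features.
a
about
above
after
again
against
all
am
an
and
any
are
aren
as
at
be
because
been
before
being
below
between
both
but
by
can
couldn
d
did
didn
do
does
doesn
doing
don
down
during
each
few
for
from
further
had
hadn
has
hasn
have
haven
having
he
her
here
hers
herself
him
himself
his
how
i
if
in
into
is
isn
it
its
itself
just
ll
m
ma
me
mightn
more
most
mustn
my
myself
needn
neither
never
no
nor
not
now
o
of
off
on
once
only
or
other
our
ours
ourselves
out
over
own
re
s
same
shan
she
should
shouldn
so
some
such
t
than
that
the
their
theirs
them
themselves
then
there
these
they
this
those
through
to
too
under
until
up
ve
very
was
wasn
we
were
weren
what
when
where
which
while
who
whom
why
will
with
won
wouldn
y
you
your
yours
yourself
yourselves
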