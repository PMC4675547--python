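# Default stopword list for term-based recurrence analysis, v1.
# One term per line; lines starting with '#' are comments.
# English function words, common contractions, minimal backchannel/interjection
# forms, and a small set of semantically empty or ambiguous conversational
# tokens ("no", "hmm", "yeah", "right", "like") that would otherwise register
# as spurious shared content between speakers.
a
about
above
after
again
against
ah
ain't
all
also
always
am
an
and
any
anything
are
aren't
around
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
ca
can
can't
cannot
could
couldn't
'cause
cause
come
comes
coming
d
dear
did
didn't
do
does
doesn't
doing
don
don't
down
during
each
eh
er
few
for
from
further
get
gets
getting
go
goes
going
gonna
got
gotta
had
hadn't
has
hasn't
have
haven't
having
he
he'd
he'll
he's
her
here
here's
hers
herself
hey
him
himself
his
hmm
hmmm
how
how's
huh
i
i'd
i'll
i'm
i've
if
in
into
is
isn't
it
it'd
it'll
it's
its
itself
just
know
let's
like
ll
lot
m
ma
me
mhm
might
mightn't
mine
mm
mmm
more
most
must
mustn't
my
myself
nah
need
needn't
never
no
nope
nor
not
now
nuh
o
of
off
oh
ok
okay
on
once
only
onto
ooh
or
other
ought
our
ours
ourselves
out
over
own
re
really
right
s
said
same
say
says
see
shall
shan't
she
she'd
she'll
she's
should
shouldn't
so
some
something
such
t
than
that
that'd
that'll
that's
the
their
theirs
them
themselves
then
there
there's
these
they
they'd
they'll
they're
they've
thing
things
this
those
through
to
too
uh
um
under
until
up
us
ve
very
was
wasn't
we
we'd
we'll
we're
we've
well
were
weren't
what
what's
when
when's
where
where's
which
while
who
who's
whom
why
why's
will
with
won't
would
wouldn't
y
yeah
yep
yes
yet
you
you'd
you'll
you're
you've
your
yours
yourself
yourselves
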